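"""Model parameter containers: event equations, utilities, decrements, costs.

A :class:`ParameterSet` bundles everything one sex's model needs:

* four first-event equations (non-fatal CHD, non-fatal CBVD, fatal CVD,
  fatal non-CVD) and two post-event death equations, each a probit on a
  linear predictor in the ASSIGN factors plus a restricted cubic spline in
  time;
* ten subsequent-event probit equations (five non-fatal CVD event types per
  post-event state);
* the background utility table (sex x 7 age bands x 5 SIMD fifths);
* the five utility decrements;
* annual hospital cost curves before and after each first event;
* a variance-covariance matrix over a declared flat parameter ordering,
  used for probabilistic sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .profiles import SEXES
from .splines import rcs_value

FIRST_EVENTS = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "fatal_non_cvd")
NONFATAL_EVENTS = ("nonfatal_chd", "nonfatal_cbvd")
FATAL_EVENTS = ("fatal_cvd", "fatal_non_cvd")
#: index of the cause that absorbs residual survival at the horizon
RESIDUAL_EVENT = "fatal_non_cvd"

POST_STATES = ("post_chd", "post_cbvd")
STATE_OF_EVENT = {"nonfatal_chd": "post_chd", "nonfatal_cbvd": "post_cbvd"}
POST_DEATH_EQS = {"post_chd": "post_chd_death", "post_cbvd": "post_cbvd_death"}

#: the five subsequent non-fatal CVD event types.  The CHD decrement is the
#: myocardial-infarction decrement; the CBVD decrement is the stroke one.
SUBSEQUENT_EVENTS = (
    "chd",
    "stroke",
    "irregular_heartbeat",
    "intermittent_claudication",
    "heart_failure",
)
FIRST_EVENT_DECREMENT = {"nonfatal_chd": "chd", "nonfatal_cbvd": "stroke"}

AGE_BAND_EDGES = (20, 25, 35, 45, 55, 65, 75)
AGE_BAND_LABELS = ("20-25", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")
N_BANDS = len(AGE_BAND_LABELS)
N_FIFTHS = 5

#: SF-6D utility scale bounds
UTILITY_MIN = 0.29
UTILITY_MAX = 1.0
#: a decrement cannot exceed the width of the utility scale
DECREMENT_MAX = UTILITY_MAX - UTILITY_MIN


def age_band_index(age) -> int | np.ndarray:
    """Half-open age band lookup: [20,25), [25,35), ..., [75, inf)."""
    age = np.asarray(age)
    if np.any(age < AGE_BAND_EDGES[0]):
        raise ValidationError(f"age below {AGE_BAND_EDGES[0]} has no utility band")
    idx = np.searchsorted(AGE_BAND_EDGES, age, side="right") - 1
    idx = np.minimum(idx, N_BANDS - 1)
    return idx if idx.ndim else int(idx)


@dataclass(frozen=True)
class EventEquation:
    """Probit event equation: intercept + betas . x + RCS(time) . coefs."""

    intercept: float
    betas: dict = field(default_factory=dict)
    spline_knots: tuple | None = None
    spline_coefs: tuple | None = None
    link: str = "probit"

    def __post_init__(self):
        if self.link != "probit":
            raise ValidationError(f"only the probit link is supported, got {self.link!r}")
        if (self.spline_knots is None) != (self.spline_coefs is None):
            raise ValidationError("spline knots and coefficients must come together")
        if self.spline_knots is not None:
            knots = tuple(float(k) for k in self.spline_knots)
            coefs = tuple(float(c) for c in self.spline_coefs)
            if len(knots) < 3:
                raise ValidationError(f"spline needs >= 3 knots, got {len(knots)}")
            if any(b <= a for a, b in zip(knots, knots[1:])):
                raise ValidationError(f"spline knots must be strictly ascending: {knots}")
            if len(coefs) != len(knots) - 1:
                raise ValidationError(
                    f"{len(knots)}-knot spline needs {len(knots) - 1} coefficients, "
                    f"got {len(coefs)}"
                )
            object.__setattr__(self, "spline_knots", knots)
            object.__setattr__(self, "spline_coefs", coefs)
        object.__setattr__(self, "intercept", float(self.intercept))
        object.__setattr__(
            self, "betas", {str(k): float(v) for k, v in self.betas.items()}
        )

    def spline_value(self, x):
        if self.spline_knots is None:
            return np.zeros(np.shape(x))
        return rcs_value(x, self.spline_knots, self.spline_coefs)

    def replace(self, **changes) -> "EventEquation":
        return dataclasses.replace(self, **changes)


class UtilityTable:
    """Background utility u(sex, age band, SIMD fifth) on the SF-6D scale.

    Values live in a (2 sexes, 7 bands, 5 fifths) array; every cell must lie
    in [0.29, 1.0].
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(SEXES), N_BANDS, N_FIFTHS):
            raise ValidationError(
                f"utility table must have shape {(len(SEXES), N_BANDS, N_FIFTHS)}, "
                f"got {values.shape}"
            )
        if np.any(values < UTILITY_MIN) or np.any(values > UTILITY_MAX):
            bad = values[(values < UTILITY_MIN) | (values > UTILITY_MAX)]
            raise ValidationError(
                f"utility values outside [{UTILITY_MIN}, {UTILITY_MAX}]: {bad[:5]}"
            )
        self.values = values

    def lookup(self, sex: str, age, simd_fifth: int):
        if sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        if not 1 <= int(simd_fifth) <= 5:
            raise ValidationError(f"simd_fifth={simd_fifth} outside 1..5")
        band = age_band_index(age)
        return self.values[SEXES.index(sex), band, int(simd_fifth) - 1]

    def to_frame(self):
        import pandas as pd

        rows = []
        for si, sex in enumerate(SEXES):
            for bi, band in enumerate(AGE_BAND_LABELS):
                for fi in range(N_FIFTHS):
                    rows.append((sex, band, fi + 1, self.values[si, bi, fi]))
        return pd.DataFrame(rows, columns=["sex", "age_band", "simd_fifth", "utility"])

    @classmethod
    def from_frame(cls, frame) -> "UtilityTable":
        values = np.full((len(SEXES), N_BANDS, N_FIFTHS), np.nan)
        for row in frame.itertuples(index=False):
            si = SEXES.index(row.sex)
            bi = AGE_BAND_LABELS.index(row.age_band)
            values[si, bi, int(row.simd_fifth) - 1] = row.utility
        if np.any(np.isnan(values)):
            raise ValidationError("utility table is missing cells (need 2x7x5 = 70)")
        return cls(values)

    def __eq__(self, other):
        return isinstance(other, UtilityTable) and np.array_equal(
            self.values, other.values
        )


@dataclass(frozen=True)
class DecrementSet:
    """Utility decrements for the five subsequent non-fatal CVD events."""

    values: dict

    def __post_init__(self):
        values = {str(k): float(v) for k, v in self.values.items()}
        missing = set(SUBSEQUENT_EVENTS) - set(values)
        if missing:
            raise ValidationError(f"decrements missing for events: {sorted(missing)}")
        for name, delta in values.items():
            if name not in SUBSEQUENT_EVENTS:
                raise ValidationError(f"unknown decrement event {name!r}")
            if not (0.0 <= delta <= DECREMENT_MAX):
                raise ValidationError(
                    f"decrement {name}={delta} outside [0, {DECREMENT_MAX}]"
                )
        object.__setattr__(self, "values", values)

    def delta(self, event: str) -> float:
        if event not in self.values:
            raise ValidationError(f"unknown decrement event {event!r}")
        return self.values[event]

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[e] for e in SUBSEQUENT_EVENTS])

    def first_event_decrement(self, first_event: str) -> float:
        """Decrement applied after a first non-fatal event (MI for CHD,
        stroke for CBVD)."""
        return self.delta(FIRST_EVENT_DECREMENT[first_event])


@dataclass(frozen=True)
class CostCurve:
    """Annual cost curve: intercept + RCS(years-since-event) + RCS(age)."""

    intercept: float
    age_knots: tuple | None = None
    age_coefs: tuple | None = None
    u_knots: tuple | None = None
    u_coefs: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "intercept", float(self.intercept))
        for pre in ("age", "u"):
            knots = getattr(self, f"{pre}_knots")
            coefs = getattr(self, f"{pre}_coefs")
            if (knots is None) != (coefs is None):
                raise ValidationError(f"{pre} knots and coefficients must come together")
            if knots is not None:
                knots = tuple(float(k) for k in knots)
                coefs = tuple(float(c) for c in coefs)
                if len(coefs) != len(knots) - 1:
                    raise ValidationError(
                        f"{len(knots)}-knot curve needs {len(knots) - 1} coefficients"
                    )
                object.__setattr__(self, f"{pre}_knots", knots)
                object.__setattr__(self, f"{pre}_coefs", coefs)

    def raw_value(self, age=None, u=None):
        total = np.asarray(self.intercept, dtype=float)
        if self.age_knots is not None:
            if age is None:
                raise ValidationError("cost curve needs an age argument")
            total = total + rcs_value(age, self.age_knots, self.age_coefs)
        if self.u_knots is not None:
            if u is None:
                raise ValidationError("cost curve needs a years-since-event argument")
            total = total + rcs_value(u, self.u_knots, self.u_coefs)
        # intercept-only curves must still broadcast over vector arguments
        args = [np.asarray(a, dtype=float) for a in (age, u) if a is not None]
        if args:
            total = total + np.zeros(np.broadcast(*args).shape)
        return total

    def replace(self, **changes) -> "CostCurve":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CostModel:
    """Pre-event cost curve (age only) and post-event curves per first event."""

    pre_event: CostCurve
    post_event: dict
    terminal_cost: float = 0.0

    def __post_init__(self):
        post = dict(self.post_event)
        missing = set(NONFATAL_EVENTS) - set(post)
        if missing:
            raise ValidationError(f"post-event cost curves missing: {sorted(missing)}")
        object.__setattr__(self, "post_event", post)
        object.__setattr__(self, "terminal_cost", float(self.terminal_cost))

    def replace(self, **changes) -> "CostModel":
        return dataclasses.replace(self, **changes)


def _check_psd(vcov: np.ndarray, tol: float = 1e-10) -> None:
    vcov = np.asarray(vcov, dtype=float)
    if vcov.ndim != 2 or vcov.shape[0] != vcov.shape[1]:
        raise ValidationError(f"vcov must be square, got shape {vcov.shape}")
    scale = max(1.0, float(np.abs(vcov).max()))
    if not np.allclose(vcov, vcov.T, atol=1e-10 * scale):
        raise ValidationError("vcov must be symmetric")
    min_eig = float(np.linalg.eigvalsh(vcov).min())
    if min_eig < -tol * scale:
        raise ValidationError(
            f"vcov is not positive semi-definite (min eigenvalue {min_eig:.3g})"
        )


@dataclass
class ParameterSet:
    """All coefficients for one sex's model, plus the PSA vcov block."""

    sex: str
    event_models: dict
    subsequent_event_models: dict
    utility_table: UtilityTable
    decrements: DecrementSet
    cost_model: CostModel
    vcov: np.ndarray | None = None
    param_names: tuple | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Structural invariant check; returns a list of violations."""
        v: list[str] = []
        if self.sex not in SEXES:
            v.append(f"sex={self.sex!r} not in {SEXES}")
        required = set(FIRST_EVENTS) | set(POST_DEATH_EQS.values())
        missing = required - set(self.event_models)
        if missing:
            v.append(f"event equations missing: {sorted(missing)}")
        for state in POST_STATES:
            eqs = self.subsequent_event_models.get(state, {})
            miss = set(SUBSEQUENT_EVENTS) - set(eqs)
            if miss:
                v.append(f"subsequent-event equations missing in {state}: {sorted(miss)}")
        if self.vcov is not None:
            try:
                _check_psd(self.vcov)
            except ValidationError as exc:
                v.append(str(exc))
            names = self.param_names
            if names is None:
                v.append("vcov present but param_names missing")
            else:
                if len(names) != np.asarray(self.vcov).shape[0]:
                    v.append(
                        f"vcov dimension {np.asarray(self.vcov).shape[0]} != "
                        f"{len(names)} parameter names"
                    )
                expected = self.parameter_ordering()
                if set(names) != set(expected):
                    extra = sorted(set(names) - set(expected))[:3]
                    miss = sorted(set(expected) - set(names))[:3]
                    v.append(
                        f"vcov ordering does not cover the equation coefficients "
                        f"(missing {miss}, extra {extra})"
                    )
        return v

    def check_valid(self) -> "ParameterSet":
        violations = self.validate()
        if violations:
            raise ValidationError("; ".join(violations))
        return self

    # -- flat parameter vector ----------------------------------------------

    def _equation_items(self):
        """Yield (name, kind, container-key tuples) in canonical order."""
        for ev in FIRST_EVENTS + tuple(POST_DEATH_EQS[s] for s in POST_STATES):
            yield ("event", ev), self.event_models[ev]
        for state in POST_STATES:
            for ev in SUBSEQUENT_EVENTS:
                yield ("subseq", state, ev), self.subsequent_event_models[state][ev]

    def parameter_ordering(self) -> tuple:
        """Canonical flat ordering of every coefficient in the set."""
        names: list[str] = []
        for key, eq in self._equation_items():
            prefix = ".".join(key)
            names.append(f"{prefix}.intercept")
            names.extend(f"{prefix}.beta.{t}" for t in eq.betas)
            if eq.spline_coefs is not None:
                names.extend(f"{prefix}.spline.{i}" for i in range(len(eq.spline_coefs)))
        names.extend(f"decrement.{e}" for e in SUBSEQUENT_EVENTS)
        names.extend(_cost_curve_names("cost.pre", self.cost_model.pre_event))
        for ev in NONFATAL_EVENTS:
            names.extend(
                _cost_curve_names(f"cost.post.{ev}", self.cost_model.post_event[ev])
            )
        for band in AGE_BAND_LABELS:
            for fifth in range(1, N_FIFTHS + 1):
                names.append(f"utility.{band}.{fifth}")
        return tuple(names)

    def parameter_vector(self) -> np.ndarray:
        vec: list[float] = []
        for _, eq in self._equation_items():
            vec.append(eq.intercept)
            vec.extend(eq.betas.values())
            if eq.spline_coefs is not None:
                vec.extend(eq.spline_coefs)
        vec.extend(self.decrements.as_vector())
        vec.extend(_cost_curve_vector(self.cost_model.pre_event))
        for ev in NONFATAL_EVENTS:
            vec.extend(_cost_curve_vector(self.cost_model.post_event[ev]))
        vec.extend(self.utility_table.values[SEXES.index(self.sex)].ravel())
        return np.array(vec, dtype=float)

    def with_parameter_vector(self, vec: np.ndarray) -> "ParameterSet":
        """Rebuild a ParameterSet with coefficients replaced from a flat
        vector in the canonical ordering (used by PSA and extremes)."""
        vec = np.asarray(vec, dtype=float)
        expected = len(self.parameter_ordering())
        if vec.shape != (expected,):
            raise ValidationError(
                f"parameter vector has length {vec.size}, expected {expected}"
            )
        pos = 0

        def take(n):
            nonlocal pos
            out = vec[pos : pos + n]
            pos += n
            return out

        def rebuild_eq(eq: EventEquation) -> EventEquation:
            intercept = float(take(1)[0])
            betas = dict(zip(eq.betas, take(len(eq.betas))))
            coefs = None
            if eq.spline_coefs is not None:
                coefs = tuple(take(len(eq.spline_coefs)))
            return eq.replace(intercept=intercept, betas=betas, spline_coefs=coefs)

        events = {}
        for ev in FIRST_EVENTS + tuple(POST_DEATH_EQS[s] for s in POST_STATES):
            events[ev] = rebuild_eq(self.event_models[ev])
        subseq = {}
        for state in POST_STATES:
            subseq[state] = {
                ev: rebuild_eq(self.subsequent_event_models[state][ev])
                for ev in SUBSEQUENT_EVENTS
            }
        decs = DecrementSet(dict(zip(SUBSEQUENT_EVENTS, take(len(SUBSEQUENT_EVENTS)))))

        def rebuild_curve(curve: CostCurve) -> CostCurve:
            # order must mirror _cost_curve_vector: intercept, u, age
            intercept = float(take(1)[0])
            u_coefs = (
                tuple(take(len(curve.u_coefs))) if curve.u_coefs is not None else None
            )
            age_coefs = (
                tuple(take(len(curve.age_coefs))) if curve.age_coefs is not None else None
            )
            return curve.replace(intercept=intercept, age_coefs=age_coefs, u_coefs=u_coefs)

        pre = rebuild_curve(self.cost_model.pre_event)
        post = {
            ev: rebuild_curve(self.cost_model.post_event[ev]) for ev in NONFATAL_EVENTS
        }
        cost_model = self.cost_model.replace(pre_event=pre, post_event=post)

        cells = take(N_BANDS * N_FIFTHS).reshape(N_BANDS, N_FIFTHS)
        if np.any(cells < UTILITY_MIN) or np.any(cells > UTILITY_MAX):
            raise ValidationError(
                f"utility values outside [{UTILITY_MIN}, {UTILITY_MAX}]"
            )
        values = self.utility_table.values.copy()
        values[SEXES.index(self.sex)] = cells
        table = UtilityTable(values)

        return dataclasses.replace(
            self,
            event_models=events,
            subsequent_event_models=subseq,
            decrements=decs,
            cost_model=cost_model,
            utility_table=table,
        )

    def standard_errors(self) -> np.ndarray:
        if self.vcov is None:
            raise ValidationError("ParameterSet has no vcov")
        return np.sqrt(np.diag(np.asarray(self.vcov, dtype=float)))


def _cost_curve_names(prefix: str, curve: CostCurve) -> list[str]:
    names = [f"{prefix}.intercept"]
    if curve.u_coefs is not None:
        names.extend(f"{prefix}.u.{i}" for i in range(len(curve.u_coefs)))
    if curve.age_coefs is not None:
        names.extend(f"{prefix}.age.{i}" for i in range(len(curve.age_coefs)))
    return names


def _cost_curve_vector(curve: CostCurve) -> list[float]:
    vec = [curve.intercept]
    if curve.u_coefs is not None:
        vec.extend(curve.u_coefs)
    if curve.age_coefs is not None:
        vec.extend(curve.age_coefs)
    return vec
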