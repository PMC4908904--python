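"""Intervention application, incremental analysis and threshold analysis.

An intervention modifies risk factors (absolute change, relative change or
set-to-value), optionally phased by an onset lag, an annual decay of the
retained effect (reversibility) and an adherence proportion.  Evaluation
runs the pre- and post-intervention profiles through the KMSA engine and
compares discounted life expectancy, QALE and costs net of intervention
costs, producing an incremental cost-effectiveness ratio (ICER) with
dominance flags.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import AnalysisError, ValidationError
from .events import first_event_distribution
from .kmsa import ExpectedOutcomes, discount_factors, expected_outcomes
from .parameters import FIRST_EVENTS, ParameterSet
from .profiles import ProfilePath, RiskProfile, RunConfig, validate_profile

#: clamping bounds when an intervention drives a factor out of range
FACTOR_BOUNDS = {
    "sbp": (50.0, 300.0),
    "total_chol": (1.0, 20.0),
    "hdl_chol": (0.3, 5.0),
    "cigarettes_per_day": (0.0, 100.0),
    "simd": (0.0, 200.0),
    "family_history": (0.0, 1.0),
    "diabetes": (0.0, 1.0),
}
MODIFIABLE_FACTORS = tuple(FACTOR_BOUNDS) + ("chol_ratio",)


@dataclass(frozen=True)
class RiskFactorChange:
    """One factor's change: kind is 'set', 'add' or 'scale'."""

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("set", "add", "scale"):
            raise ValidationError(f"unknown change kind {self.kind!r}")
        object.__setattr__(self, "value", float(self.value))

    def target(self, base: float) -> float:
        if self.kind == "set":
            return self.value
        if self.kind == "add":
            return base + self.value
        return base * self.value


@dataclass(frozen=True)
class Intervention:
    """Risk-factor changes plus costs, lag, reversibility and adherence.

    ``changes`` maps factor name to a :class:`RiskFactorChange` (a bare
    number is shorthand for an absolute 'add' change).  ``annual_decay`` is
    the proportion of the achieved change lost each year after onset
    (0 = permanent).  ``adherence`` multiplies the expected change
    (cohort-expectation interpretation; see ``adherence_mode`` in
    :func:`evaluate_intervention` for the Bernoulli-mixture reading).
    """

    changes: dict = field(default_factory=dict)
    onset_lag: int = 0
    annual_decay: float = 0.0
    adherence: float = 1.0
    one_off_cost: float = 0.0
    annual_cost: float = 0.0
    label: str = ""

    def __post_init__(self):
        norm = {}
        for factor, change in self.changes.items():
            if factor not in MODIFIABLE_FACTORS:
                raise ValidationError(f"cannot intervene on factor {factor!r}")
            if not isinstance(change, RiskFactorChange):
                change = RiskFactorChange("add", change)
            norm[factor] = change
        object.__setattr__(self, "changes", norm)
        if not (0.0 <= self.adherence <= 1.0):
            raise ValidationError(f"adherence={self.adherence} outside [0, 1]")
        if not (0.0 <= self.annual_decay <= 1.0):
            raise ValidationError(f"annual_decay={self.annual_decay} outside [0, 1]")
        if self.onset_lag < 0:
            raise ValidationError("onset_lag must be >= 0")

    @property
    def is_static(self) -> bool:
        return self.onset_lag == 0 and self.annual_decay == 0.0

    def scaled(self, s: float) -> "Intervention":
        """Intervention with effect sizes scaled by ``s`` in [0, 1].

        Scaling interpolates between the baseline profile (s = 0) and the
        fully realised change (s = 1), uniformly across change kinds.
        """
        out = Intervention(
            changes=self.changes,
            onset_lag=self.onset_lag,
            annual_decay=self.annual_decay,
            adherence=self.adherence,
            one_off_cost=self.one_off_cost,
            annual_cost=self.annual_cost,
            label=self.label,
        )
        object.__setattr__(out, "_effect_scale", float(s))
        return out


def _effect_scale(intervention: Intervention) -> float:
    return getattr(intervention, "_effect_scale", 1.0)


def _clamp(factor: str, value: float, warnings_out: list) -> float:
    lo, hi = FACTOR_BOUNDS[factor]
    if value < lo or value > hi:
        clamped = min(max(value, lo), hi)
        msg = f"intervention drove {factor} to {value:.4g}; clamped to {clamped:.4g}"
        warnings_out.append(msg)
        _warnings.warn(msg, stacklevel=3)
        return clamped
    return value


def _modified_profile(
    profile: RiskProfile, intervention: Intervention, fraction: float, warnings_out: list
) -> RiskProfile:
    """Profile with the expected change applied at retention ``fraction``."""
    fraction *= _effect_scale(intervention)
    updates = {}
    for factor, change in intervention.changes.items():
        if factor == "chol_ratio":
            # a ratio change adjusts total cholesterol, holding HDL fixed
            base_ratio = profile.chol_ratio
            target_ratio = change.target(base_ratio)
            new_ratio = base_ratio + fraction * (target_ratio - base_ratio)
            updates["total_chol"] = _clamp(
                "total_chol", new_ratio * profile.hdl_chol, warnings_out
            )
            continue
        base = getattr(profile, factor)
        target = change.target(base)
        updates[factor] = _clamp(factor, base + fraction * (target - base), warnings_out)
    modified = profile.replace(**updates)
    bad = validate_profile(modified)
    if bad:
        raise ValidationError(
            "intervention produced an invalid profile: " + "; ".join(bad)
        )
    return modified


def apply_intervention(
    profile: RiskProfile,
    intervention: Intervention,
    horizon: int = 100,
):
    """Modified risk profile, or a :class:`ProfilePath` when time-varying.

    The expected change is adherence x stated change, zero before the onset
    lag and decaying geometrically afterwards at the annual decay rate.
    With the defaults (lag 0, decay 0, adherence 1) the change is immediate
    and permanent and a single profile is returned.  Out-of-range values are
    clamped to the factor's bounds with a warning record.
    """
    warnings_out: list = []
    a = intervention.adherence
    if intervention.is_static:
        modified = _modified_profile(profile, intervention, a, warnings_out)
        if warnings_out:
            return ProfilePath([modified], warnings=warnings_out)
        return modified
    profiles = []
    for k in range(horizon + 1):
        if k < intervention.onset_lag:
            frac = 0.0
        else:
            frac = a * (1.0 - intervention.annual_decay) ** (k - intervention.onset_lag)
        profiles.append(_modified_profile(profile, intervention, frac, warnings_out))
    return ProfilePath(profiles, warnings=warnings_out)


@dataclass
class EconResult:
    """Baseline vs modified outcomes and the incremental comparison.

    ``delta_cost`` is net of (discounted) intervention costs; ``icer`` is
    cost per QALY gained, or None with ``flag`` in {dominant, dominated,
    undefined}.
    """

    baseline: ExpectedOutcomes
    modified: ExpectedOutcomes
    delta_le: float
    delta_qale: float
    delta_cost: float
    delta_le_disc: float
    delta_qale_disc: float
    delta_cost_disc: float
    intervention_cost_disc: float
    icer: float | None
    flag: str


def _icer_and_flag(delta_qale: float, delta_cost: float):
    if delta_qale > 0 and delta_cost > 0:
        return delta_cost / delta_qale, "icer"
    if delta_qale > 0:
        return None, "dominant"
    if delta_qale < 0 and delta_cost >= 0:
        return None, "dominated"
    return None, "undefined"


def intervention_cost(
    intervention: Intervention, occupancy: np.ndarray, rate: float
) -> tuple[float, float]:
    """(undiscounted, discounted) intervention cost for one cohort run.

    The one-off cost falls in the first cycle; annual costs are paid while
    alive (mid-cycle occupancy weighting, like hospital costs).
    """
    T = len(occupancy)
    df = discount_factors(T, rate)
    und = intervention.one_off_cost + intervention.annual_cost * float(occupancy.sum())
    dis = intervention.one_off_cost * float(df[0]) + intervention.annual_cost * float(
        occupancy @ df
    )
    return und, dis


def evaluate_intervention(
    profile: RiskProfile,
    intervention: Intervention,
    params: ParameterSet,
    config: RunConfig | None = None,
    *,
    adherence_mode: str = "expected",
) -> EconResult:
    """Run baseline and post-intervention cohorts and compare.

    ``adherence_mode='expected'`` applies adherence as a multiplier on the
    risk-factor change; ``'mixture'`` evaluates a Bernoulli mixture of full
    adherers and non-adherers and mixes the outcomes.
    """
    config = config or RunConfig()
    if adherence_mode not in ("expected", "mixture"):
        raise ValidationError(f"unknown adherence_mode {adherence_mode!r}")
    baseline = expected_outcomes(profile, params, config)

    if adherence_mode == "expected":
        modified_input = apply_intervention(profile, intervention, config.horizon)
        modified = expected_outcomes(modified_input, params, config)
    else:
        full = Intervention(
            changes=intervention.changes,
            onset_lag=intervention.onset_lag,
            annual_decay=intervention.annual_decay,
            adherence=1.0,
            one_off_cost=intervention.one_off_cost,
            annual_cost=intervention.annual_cost,
            label=intervention.label,
        )
        object.__setattr__(full, "_effect_scale", _effect_scale(intervention))
        adherer = expected_outcomes(
            apply_intervention(profile, full, config.horizon), params, config
        )
        a = intervention.adherence
        modified = ExpectedOutcomes(
            life_expectancy=a * adherer.life_expectancy
            + (1 - a) * baseline.life_expectancy,
            qale=a * adherer.qale + (1 - a) * baseline.qale,
            lifetime_cost=a * adherer.lifetime_cost + (1 - a) * baseline.lifetime_cost,
            life_expectancy_disc=a * adherer.life_expectancy_disc
            + (1 - a) * baseline.life_expectancy_disc,
            qale_disc=a * adherer.qale_disc + (1 - a) * baseline.qale_disc,
            lifetime_cost_disc=a * adherer.lifetime_cost_disc
            + (1 - a) * baseline.lifetime_cost_disc,
            distribution=adherer.distribution,
            scenario_grid=adherer.scenario_grid,
            expected_occupancy=a * adherer.expected_occupancy
            + (1 - a) * baseline.expected_occupancy,
            config=config,
        )

    iv_und, iv_dis = intervention_cost(
        intervention, modified.expected_occupancy, config.cost_rate
    )
    delta_qale_disc = modified.qale_disc - baseline.qale_disc
    delta_cost_disc = modified.lifetime_cost_disc - baseline.lifetime_cost_disc + iv_dis
    icer, flag = _icer_and_flag(delta_qale_disc, delta_cost_disc)
    return EconResult(
        baseline=baseline,
        modified=modified,
        delta_le=modified.life_expectancy - baseline.life_expectancy,
        delta_qale=modified.qale - baseline.qale,
        delta_cost=modified.lifetime_cost - baseline.lifetime_cost + iv_und,
        delta_le_disc=modified.life_expectancy_disc - baseline.life_expectancy_disc,
        delta_qale_disc=delta_qale_disc,
        delta_cost_disc=delta_cost_disc,
        intervention_cost_disc=iv_dis,
        icer=icer,
        flag=flag,
    )


def threshold_analysis(
    profile: RiskProfile,
    intervention: Intervention,
    params: ParameterSet,
    config: RunConfig | None = None,
    *,
    vary: str = "cost",
    willingness_to_pay: float = 20000.0,
    bracket_max: float = 1e9,
) -> float:
    """Breakeven intervention cost or effect scale at a willingness to pay.

    Finds the varied quantity where the ICER equals the willingness to pay,
    i.e. where the net monetary benefit lambda*dQALE - dcost crosses zero,
    by bisection to 1e-6 relative tolerance.  Raises when the bracket shows
    no sign change (non-monotone or unreachable configuration).
    """
    config = config or RunConfig()

    if vary == "cost":
        def nmb(c):
            iv = Intervention(
                changes=intervention.changes,
                onset_lag=intervention.onset_lag,
                annual_decay=intervention.annual_decay,
                adherence=intervention.adherence,
                one_off_cost=c,
                annual_cost=intervention.annual_cost,
                label=intervention.label,
            )
            object.__setattr__(iv, "_effect_scale", _effect_scale(intervention))
            res = evaluate_intervention(profile, iv, params, config)
            return willingness_to_pay * res.delta_qale_disc - res.delta_cost_disc

        lo, hi = 0.0, max(1.0, abs(intervention.one_off_cost) * 2)
        f_lo = nmb(lo)
        if f_lo <= 0:
            raise AnalysisError(
                "intervention is not cost-effective even at zero cost: no "
                "non-negative breakeven cost exists"
            )
        f_hi = nmb(hi)
        while f_hi > 0 and hi < bracket_max:
            hi *= 4
            f_hi = nmb(hi)
        if f_hi > 0:
            raise AnalysisError("no sign change in bracket when varying cost")
        return float(brentq(nmb, lo, hi, xtol=1e-9, rtol=1e-12))

    if vary == "effect":
        def nmb(s):
            res = evaluate_intervention(profile, intervention.scaled(s), params, config)
            return willingness_to_pay * res.delta_qale_disc - res.delta_cost_disc

        lo, hi = 0.0, 1.0
        f_lo, f_hi = nmb(lo), nmb(hi)
        if f_hi == 0.0:
            return hi
        if f_lo * f_hi > 0 or (f_lo == 0.0 and f_hi > 0):
            # a cost-free intervention has NMB exactly 0 at scale 0; a
            # positive NMB at full scale then leaves no genuine crossing
            raise AnalysisError(
                "no sign change in bracket when varying effect scale in [0, 1]"
            )
        return float(brentq(nmb, lo, hi, xtol=1e-10, rtol=1e-12))

    raise ValidationError(f"vary must be 'cost' or 'effect', got {vary!r}")


def event_rate_to_risk_factor(
    profile: RiskProfile,
    params: ParameterSet,
    event: str,
    target_change: float,
    factor: str,
    config: RunConfig | None = None,
) -> float:
    """Risk-factor change reproducing a target proportional change in an
    event's lifetime incidence.

    ``target_change`` is proportional (-0.10 = 10% fewer first events of
    ``event``).  Returns the additive change to ``factor`` whose incidence,
    re-evaluated through the competing-risk engine, matches the target to
    1e-6.  Raises when the target is unreachable within the factor's valid
    range.
    """
    config = config or RunConfig()
    if event not in FIRST_EVENTS:
        raise ValidationError(f"unknown first event {event!r}")
    if factor not in FACTOR_BOUNDS:
        raise ValidationError(f"cannot vary factor {factor!r}")
    base_value = getattr(profile, factor)
    current = first_event_distribution(profile, params, config.horizon).total_incidence(
        event
    )
    target = (1.0 + target_change) * current
    if target_change == 0:
        return 0.0

    lo_bound, hi_bound = FACTOR_BOUNDS[factor]

    def gap(delta):
        candidate = profile.replace(**{factor: base_value + delta})
        inc = first_event_distribution(
            candidate, params, config.horizon
        ).total_incidence(event)
        return inc - target

    lo, hi = lo_bound - base_value, hi_bound - base_value
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise AnalysisError(
            f"target incidence change {target_change:+.3g} for {event} is "
            f"unreachable within {factor}'s valid range [{lo_bound}, {hi_bound}]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12))
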