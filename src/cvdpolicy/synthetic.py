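"""Synthetic data generators and independent estimation oracles.

Everything the real data sources would supply is generated here with known
truth: parameter sets whose event curves rise with age towards a plateau
(calibrated so a reference individual's cumulative first-event incidence by
cycle 40 falls in [0.5, 0.99]), health-survey-like utility records, cohort
event histories simulated exactly from the discrete-time equations, and
hospitalisation cost panels.

Two oracles validate the KMSA engine: a Monte-Carlo microsimulation that
realises individual paths cycle by cycle, and an exact enumerator over
first events and post-event death times (subsequent-event indicators are
independent of the death draws and enter utility linearly, so the
enumerator sums each indicator's two outcomes exactly per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ValidationError
from .events import first_event_distribution
from .parameters import (
    FATAL_EVENTS,
    FIRST_EVENTS,
    NONFATAL_EVENTS,
    POST_DEATH_EQS,
    POST_STATES,
    STATE_OF_EVENT,
    SUBSEQUENT_EVENTS,
    AGE_BAND_LABELS,
    CostCurve,
    CostModel,
    DecrementSet,
    EventEquation,
    ParameterSet,
    UtilityTable,
    age_band_index,
)
from .profiles import RiskProfile, RunConfig, SEXES
from .splines import rcs_basis, rcs_value

__all__ = [
    "SyntheticTruth",
    "MicrosimEstimate",
    "make_synthetic_params",
    "make_survey_records",
    "recover_decrements",
    "make_event_histories",
    "recover_subsequent_equation",
    "make_cost_panel",
    "make_cis_year",
    "microsim_oracle",
    "enumerate_outcomes",
    "reference_profile",
]

#: decrement truth before jitter (CHD uses the myocardial-infarction value)
_BASE_DECREMENTS = {
    "chd": 0.06,
    "stroke": 0.12,
    "irregular_heartbeat": 0.05,
    "intermittent_claudication": 0.04,
    "heart_failure": 0.10,
}

_CYCLE_KNOTS = (2.0, 12.0, 30.0, 50.0, 75.0)
_POST_U_KNOTS = (0.5, 2.0, 6.0, 15.0)
_SUBSEQ_U_KNOTS = (0.5, 3.0, 9.0, 20.0)
_COST_AGE_KNOTS = (30.0, 45.0, 60.0, 75.0, 90.0)
_COST_U_KNOTS = (0.25, 1.0, 3.0, 8.0)


def reference_profile(sex: str = "male") -> RiskProfile:
    """The profile the generator calibrates against (median risk factors)."""
    return RiskProfile(
        age=60,
        sex=sex,
        simd=17.0,
        family_history=0.0,
        diabetes=0.0,
        sbp=130.0,
        total_chol=5.5,
        hdl_chol=1.3,
        cigarettes_per_day=0.0,
    )


@dataclass
class SyntheticTruth:
    """The generating parameter set plus the generator's noise scales."""

    params: ParameterSet
    seed: int
    difficulty: str
    sex: str
    survey_noise_sd: float = 0.1
    cost_noise_sd: float = 300.0
    reference: RiskProfile = None

    def __post_init__(self):
        if self.reference is None:
            self.reference = reference_profile(self.sex)


def _fit_time_curve(grid: np.ndarray, target: np.ndarray, knots, weights=None):
    """Least-squares fit of intercept + RCS(grid) . c to a target curve."""
    X = np.column_stack([np.ones_like(grid), rcs_basis(grid, knots)])
    if weights is not None:
        w = np.sqrt(weights)
        X = X * w[:, None]
        target = target * w
    sol, *_ = np.linalg.lstsq(X, target, rcond=None)
    return float(sol[0]), tuple(float(c) for c in sol[1:])


def _ref_shift(betas: dict, ref: RiskProfile, age: float) -> float:
    from .profiles import term_value

    return sum(b * term_value(ref, t, age=age) for t, b in betas.items())


def _first_event_equation(
    rng: np.random.Generator,
    betas: dict,
    q0: float,
    qcap: float,
    ref: RiskProfile,
) -> EventEquation:
    """Probit first-event equation whose linear predictor (at the reference
    profile) ramps from Phi^-1(q0) to a plateau near Phi^-1(qcap)."""
    betas = {t: b * (1 + 0.1 * rng.uniform(-1, 1)) for t, b in betas.items()}
    z0 = ndtri(q0) + 0.10 * rng.uniform(-1, 1)
    zcap = ndtri(qcap) + 0.05 * rng.uniform(-1, 1)
    t = np.arange(100, dtype=float)
    ramp = np.minimum(1.0, (t / 55.0) ** 1.2)
    target = z0 + (zcap - z0) * ramp - 0.004 * np.maximum(0.0, t - 60.0)
    b_age = betas.get("age", 0.0)
    resid = target - b_age * (ref.age + t)
    intercept, coefs = _fit_time_curve(t, resid, _CYCLE_KNOTS)
    intercept -= _ref_shift({k: v for k, v in betas.items() if k != "age"}, ref, ref.age)
    return EventEquation(
        intercept=intercept,
        betas=betas,
        spline_knots=_CYCLE_KNOTS,
        spline_coefs=coefs,
    )


def _anchored_u_equation(
    rng: np.random.Generator,
    betas: dict,
    anchors_u,
    anchors_q,
    knots,
    ref: RiskProfile,
    jitter: float = 0.08,
) -> EventEquation:
    """Probit equation in years-since-event with anchored annual
    probabilities at the reference profile (event at the reference age)."""
    betas = {t: b * (1 + 0.1 * rng.uniform(-1, 1)) for t, b in betas.items()}
    anchors_u = np.asarray(anchors_u, dtype=float)
    z_anchor = ndtri(np.asarray(anchors_q, dtype=float))
    z_anchor = z_anchor + jitter * rng.uniform(-1, 1, size=z_anchor.size)
    u = np.arange(0, 61, dtype=float)
    target = np.interp(u, anchors_u, z_anchor)
    b_age = betas.get("age", 0.0)
    resid = target - b_age * (ref.age + u)
    intercept, coefs = _fit_time_curve(u, resid, knots)
    intercept -= _ref_shift({k: v for k, v in betas.items() if k != "age"}, ref, ref.age)
    return EventEquation(
        intercept=intercept, betas=betas, spline_knots=knots, spline_coefs=coefs
    )


def _utility_values(rng: np.random.Generator, difficulty: str) -> np.ndarray:
    band_base = np.array([0.88, 0.87, 0.855, 0.835, 0.81, 0.78, 0.72])
    values = np.empty((len(SEXES), 7, 5))
    for si, sex in enumerate(SEXES):
        sex_adj = 0.0 if sex == "male" else -0.005
        for fi in range(5):
            values[si, :, fi] = (
                band_base + sex_adj - 0.012 * fi + rng.uniform(-0.008, 0.008, size=7)
            )
    if difficulty == "adversarial":
        # near-boundary utilities: oldest, most deprived cells at the floor
        values[:, -1, -1] = 0.30
        values[:, -1, -2] = 0.31
    return np.clip(values, 0.29, 1.0)


def _cost_model(rng: np.random.Generator) -> CostModel:
    ages = np.arange(20, 111, dtype=float)
    scale = 1 + 0.1 * rng.uniform(-1, 1)
    pre_target = scale * (120.0 + 4.0 * (ages - 20.0) + 55.0 * np.maximum(ages - 65.0, 0.0))
    pre_i, pre_c = _fit_time_curve(ages, pre_target, _COST_AGE_KNOTS)
    pre = CostCurve(intercept=pre_i, age_knots=_COST_AGE_KNOTS, age_coefs=pre_c)

    post = {}
    acute = {"nonfatal_chd": 4200.0, "nonfatal_cbvd": 5200.0}
    for ev in NONFATAL_EVENTS:
        u = np.arange(0, 61, dtype=float)
        s = 1 + 0.1 * rng.uniform(-1, 1)
        u_target = s * acute[ev] * np.exp(-2.0 * u)
        weights = 1.0 / (1.0 + u) ** 2
        u_i, u_c = _fit_time_curve(u, u_target, _COST_U_KNOTS, weights=weights)
        age_target = s * (300.0 + 6.0 * (ages - 20.0) + 95.0 * np.maximum(ages - 68.0, 0.0))
        a_i, a_c = _fit_time_curve(ages, age_target, _COST_AGE_KNOTS)
        post[ev] = CostCurve(
            intercept=u_i + a_i,
            u_knots=_COST_U_KNOTS,
            u_coefs=u_c,
            age_knots=_COST_AGE_KNOTS,
            age_coefs=a_c,
        )
    return CostModel(pre_event=pre, post_event=post)


def _block_vcov(rng: np.random.Generator, ses: np.ndarray, near_singular: bool) -> np.ndarray:
    k = ses.size
    if k == 1:
        R = np.ones((1, 1))
    else:
        B = rng.normal(size=(k, k + 3))
        if near_singular:
            B[1] = B[0] + 1e-5 * rng.normal(size=k + 3)
        M = B @ B.T
        d = np.sqrt(np.diag(M))
        R = M / np.outer(d, d)
    return R * np.outer(ses, ses)


def _build_vcov(params: ParameterSet, rng: np.random.Generator, difficulty: str):
    names = params.parameter_ordering()
    vec = params.parameter_vector()
    n = len(names)
    vcov = np.zeros((n, n))
    # group indices by block: one block per equation / component prefix
    blocks: dict[str, list[int]] = {}
    for i, name in enumerate(names):
        parts = name.split(".")
        if name.startswith(("event.", "cost.post.")):
            prefix = ".".join(parts[:2]) if parts[0] == "event" else ".".join(parts[:3])
        elif name.startswith("subseq."):
            prefix = ".".join(parts[:3])
        elif name.startswith("cost.pre"):
            prefix = "cost.pre"
        elif name.startswith("decrement."):
            prefix = "decrements"
        else:
            prefix = f"utility.{i}"  # utilities independent
        blocks.setdefault(prefix, []).append(i)

    singular_done = False
    for prefix, idx in blocks.items():
        idx = np.asarray(idx)
        vals = vec[idx]
        if prefix.startswith("cost"):
            ses = np.maximum(0.04 * np.abs(vals), 2.0)
        elif prefix == "decrements":
            ses = np.maximum(0.08 * np.abs(vals), 0.002)
        elif prefix.startswith("utility"):
            ses = np.full(idx.size, 0.006)
        else:
            ses = np.maximum(0.04 * np.abs(vals), 0.004)
        near_singular = (
            difficulty == "adversarial"
            and not singular_done
            and prefix.startswith("event.")
            and idx.size > 2
        )
        if near_singular:
            singular_done = True
        vcov[np.ix_(idx, idx)] = _block_vcov(rng, ses, near_singular)
    return names, vcov


def make_synthetic_params(
    seed: int,
    difficulty: str = "plain",
    *,
    sex: str = "male",
    decrement_events=None,
) -> tuple[ParameterSet, SyntheticTruth]:
    """Generate a full parameter set with known truth.

    ``difficulty='plain'`` gives monotone-signed coefficients (raising a
    hazardous factor raises the matching event's incidence);
    ``'adversarial'`` additionally pushes utilities to the 0.30 floor and
    makes one vcov block near-singular (condition number > 1e6).
    ``decrement_events`` restricts which subsequent events carry a non-zero
    decrement (all five by default).
    """
    if difficulty not in ("plain", "adversarial"):
        raise ValidationError(f"unknown difficulty {difficulty!r}")
    rng = np.random.default_rng(seed)
    ref = reference_profile(sex)
    female = 1.0 if sex == "female" else 0.0

    event_models = {
        "nonfatal_chd": _first_event_equation(
            rng,
            dict(age=0.010, sbp=0.0015, chol_ratio=0.015, cigarettes_per_day=0.004,
                 diabetes=0.12, family_history=0.06, simd_fifth=0.008),
            q0=0.004 * (1 - 0.25 * female),
            qcap=0.06 * (1 - 0.25 * female),
            ref=ref,
        ),
        "nonfatal_cbvd": _first_event_equation(
            rng,
            dict(age=0.010, sbp=0.002, cigarettes_per_day=0.004,
                 diabetes=0.10, family_history=0.04, simd_fifth=0.008),
            q0=0.0025 * (1 - 0.15 * female),
            qcap=0.04 * (1 - 0.15 * female),
            ref=ref,
        ),
        "fatal_cvd": _first_event_equation(
            rng,
            dict(age=0.010, sbp=0.0018, chol_ratio=0.012, cigarettes_per_day=0.005,
                 diabetes=0.12, family_history=0.05, simd_fifth=0.010),
            q0=0.003 * (1 - 0.25 * female),
            qcap=0.05 * (1 - 0.25 * female),
            ref=ref,
        ),
        "fatal_non_cvd": _first_event_equation(
            rng,
            dict(age=0.010, cigarettes_per_day=0.006, diabetes=0.05, simd_fifth=0.012),
            q0=0.008 * (1 - 0.1 * female),
            qcap=0.18 * (1 - 0.1 * female),
            ref=ref,
        ),
        "post_chd_death": _anchored_u_equation(
            rng,
            dict(age=0.010, cigarettes_per_day=0.003, diabetes=0.08, simd_fifth=0.006),
            anchors_u=(0, 2, 6, 15, 30, 60),
            anchors_q=(0.10, 0.045, 0.035, 0.045, 0.07, 0.12),
            knots=_POST_U_KNOTS,
            ref=ref,
        ),
        "post_cbvd_death": _anchored_u_equation(
            rng,
            dict(age=0.010, cigarettes_per_day=0.003, diabetes=0.08, simd_fifth=0.006),
            anchors_u=(0, 2, 6, 15, 30, 60),
            anchors_q=(0.13, 0.05, 0.04, 0.05, 0.08, 0.13),
            knots=_POST_U_KNOTS,
            ref=ref,
        ),
    }

    subsequent = {}
    for state in POST_STATES:
        own = "chd" if state == "post_chd" else "stroke"
        eqs = {}
        for ev in SUBSEQUENT_EVENTS:
            if ev == own:
                anchors_q = (0.07, 0.045, 0.05, 0.06)
            elif ev == "heart_failure":
                anchors_q = (0.02, 0.025, 0.035, 0.05)
            else:
                anchors_q = (0.025, 0.02, 0.025, 0.03)
            eqs[ev] = _anchored_u_equation(
                rng,
                dict(age=0.008),
                anchors_u=(0, 3, 9, 20),
                anchors_q=anchors_q,
                knots=_SUBSEQ_U_KNOTS,
                ref=ref,
            )
        subsequent[state] = eqs

    active = set(decrement_events) if decrement_events is not None else set(SUBSEQUENT_EVENTS)
    unknown = active - set(SUBSEQUENT_EVENTS)
    if unknown:
        raise ValidationError(f"unknown decrement events: {sorted(unknown)}")
    decrements = DecrementSet(
        {
            ev: (_BASE_DECREMENTS[ev] * (1 + 0.1 * rng.uniform(-1, 1)) if ev in active else 0.0)
            for ev in SUBSEQUENT_EVENTS
        }
    )

    table = UtilityTable(_utility_values(rng, difficulty))
    cost_model = _cost_model(rng)

    params = ParameterSet(
        sex=sex,
        event_models=event_models,
        subsequent_event_models=subsequent,
        utility_table=table,
        decrements=decrements,
        cost_model=cost_model,
        label=f"synthetic-{difficulty}-seed{seed}",
        metadata={"seed": int(seed), "difficulty": difficulty},
    )

    _calibrate_incidence(params, ref)

    names, vcov = _build_vcov(params, rng, difficulty)
    params.vcov = vcov
    params.param_names = names
    params.check_valid()
    truth = SyntheticTruth(params=params, seed=seed, difficulty=difficulty, sex=sex)
    return params, truth


def _calibrate_incidence(params: ParameterSet, ref: RiskProfile) -> None:
    """Shift all first-event intercepts jointly so the reference profile's
    cumulative first-event incidence by cycle 40 lands in [0.5, 0.99]."""

    def cum40(shift: float) -> float:
        shifted = {
            name: (
                eq.replace(intercept=eq.intercept + shift)
                if name in FIRST_EVENTS
                else eq
            )
            for name, eq in params.event_models.items()
        }
        probe = ParameterSet(
            sex=params.sex,
            event_models=shifted,
            subsequent_event_models=params.subsequent_event_models,
            utility_table=params.utility_table,
            decrements=params.decrements,
            cost_model=params.cost_model,
        )
        dist = first_event_distribution(ref, probe, horizon=40)
        return 1.0 - float(dist.S[-1])

    if 0.5 <= cum40(0.0) <= 0.99:
        return
    lo, hi = -0.5, 0.5
    target = 0.93
    f_lo, f_hi = cum40(lo), cum40(hi)
    if not (f_lo < target < f_hi):
        raise ValidationError("incidence calibration failed: target outside bracket")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cum40(mid) < target:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    for name in FIRST_EVENTS:
        eq = params.event_models[name]
        params.event_models[name] = eq.replace(intercept=eq.intercept + shift)


# ---------------------------------------------------------------------------
# survey and cohort generators
# ---------------------------------------------------------------------------

_DEFAULT_PREVALENCE = {
    "chd": 0.06,
    "stroke": 0.035,
    "irregular_heartbeat": 0.08,
    "intermittent_claudication": 0.03,
    "heart_failure": 0.025,
}


def _unwrap(truth) -> ParameterSet:
    return truth.params if isinstance(truth, SyntheticTruth) else truth


def make_survey_records(
    n: int = 7054,
    truth=None,
    noise_sd: float = 0.1,
    seed: int = 0,
    prevalence: dict | None = None,
) -> pd.DataFrame:
    """Cross-sectional health-survey records on the SF-6D utility scale.

    Each record carries sex, age, SIMD fifth, five event flags and a
    utility score = background utility - sum(flag * decrement) + Gaussian
    noise, clipped to [0.29, 1].
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    params = _unwrap(truth) if truth is not None else make_synthetic_params(0)[0]
    prevalence = prevalence or _DEFAULT_PREVALENCE
    rng = np.random.default_rng(seed)
    sex_idx = rng.integers(0, 2, size=n)
    age = rng.integers(20, 91, size=n)
    fifth = rng.integers(1, 6, size=n)
    bands = age_band_index(age)
    bg = params.utility_table.values[sex_idx, bands, fifth - 1]
    utility = bg + rng.normal(0.0, noise_sd, size=n)
    data = {
        "sex": np.array(SEXES)[sex_idx],
        "age": age,
        "simd_fifth": fifth,
    }
    for ev in SUBSEQUENT_EVENTS:
        flag = rng.random(n) < prevalence[ev]
        data[ev] = flag.astype(int)
        utility = utility - flag * params.decrements.delta(ev)
    data["utility"] = np.clip(utility, 0.29, 1.0)
    return pd.DataFrame(data)


def recover_decrements(records: pd.DataFrame):
    """OLS recovery of the five decrements from survey records.

    The design holds one dummy per observed (sex, age band, SIMD fifth)
    cell plus the five event flags; returns ``(estimates, ses, fit)`` with
    decrement estimates as positive numbers.
    """
    from .utilities import fit_ols

    bands = age_band_index(records["age"].to_numpy())
    cell = (
        records["sex"].astype(str)
        + "|"
        + pd.Series(np.asarray(AGE_BAND_LABELS)[bands], index=records.index)
        + "|"
        + records["simd_fifth"].astype(str)
    )
    dummies = pd.get_dummies(cell).to_numpy(dtype=float)
    flags = records[list(SUBSEQUENT_EVENTS)].to_numpy(dtype=float)
    X = np.column_stack([dummies, flags])
    fit = fit_ols(X, records["utility"].to_numpy(dtype=float))
    k = dummies.shape[1]
    estimates = {ev: -fit.params[k + j] for j, ev in enumerate(SUBSEQUENT_EVENTS)}
    ses = {ev: fit.se[k + j] for j, ev in enumerate(SUBSEQUENT_EVENTS)}
    return estimates, ses, fit


def make_profiles(n: int, seed: int = 0, sex: str = "male") -> list[RiskProfile]:
    """Random plausible risk profiles for cohort simulation."""
    rng = np.random.default_rng(seed)
    ages = rng.integers(35, 66, size=n)
    sbp = np.clip(rng.normal(135, 18, size=n), 90, 210)
    tc = np.clip(rng.normal(5.8, 1.1, size=n), 3.0, 10.0)
    hdl = np.clip(rng.normal(1.35, 0.3, size=n), 0.7, 2.5)
    tc = np.maximum(tc, hdl + 0.1)
    smoker = rng.random(n) < 0.45
    cigs = np.where(smoker, np.clip(rng.poisson(15, size=n), 1, 60), 0)
    fh = (rng.random(n) < 0.26).astype(float)
    db = (rng.random(n) < 0.10).astype(float)
    simd = rng.uniform(0.0, 60.0, size=n)
    return [
        RiskProfile(
            age=int(ages[i]),
            sex=sex,
            simd=float(simd[i]),
            family_history=float(fh[i]),
            diabetes=float(db[i]),
            sbp=float(sbp[i]),
            total_chol=float(tc[i]),
            hdl_chol=float(hdl[i]),
            cigarettes_per_day=float(cigs[i]),
        )
        for i in range(n)
    ]


def _profile_constants(profiles, eq: EventEquation) -> np.ndarray:
    """Per-person linear-predictor part excluding intercept, age and spline."""
    from .profiles import term_value

    out = np.zeros(len(profiles))
    for term, beta in eq.betas.items():
        if term == "age":
            continue
        out += beta * np.array([term_value(p, term) for p in profiles])
    return out


def make_event_histories(
    n: int = 16000,
    truth=None,
    seed: int = 0,
    follow_up: int = 21,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort exactly from the discrete-time equations.

    Returns ``(first_events, post_cycles)``: one row per person with the
    first event type/cycle (or censoring), and one row per post-event
    person-year with the attained age, years since the first event, the
    five subsequent-event flags and the death indicator.
    """
    params = _unwrap(truth) if truth is not None else make_synthetic_params(0)[0]
    rng = np.random.default_rng(seed)
    profiles = make_profiles(n, seed=seed + 1, sex=params.sex)
    ages0 = np.array([p.age for p in profiles], dtype=float)
    T = follow_up

    # first-event phase: q[person, cycle, event]
    q = np.zeros((n, T, len(FIRST_EVENTS)))
    for j, ev in enumerate(FIRST_EVENTS):
        eq = params.event_models[ev]
        const = eq.intercept + _profile_constants(profiles, eq)
        b_age = eq.betas.get("age", 0.0)
        t = np.arange(T, dtype=float)
        spline = eq.spline_value(t) if eq.spline_knots is not None else np.zeros(T)
        q[:, :, j] = ndtr(const[:, None] + b_age * (ages0[:, None] + t[None, :]) + spline[None, :])

    first_event = np.full(n, -1)
    first_cycle = np.full(n, -1)
    active = np.ones(n, dtype=bool)
    for t in range(T):
        if not active.any():
            break
        r = rng.random(n)
        cum = np.cumsum(q[:, t, :], axis=1)
        ev = (r[:, None] >= cum).sum(axis=1)  # 4 = no event this cycle
        hit = active & (ev < 4)
        first_event[hit] = ev[hit]
        first_cycle[hit] = t
        active[hit] = False

    first_df = pd.DataFrame(
        {
            "person": np.arange(n),
            "first_event": [
                FIRST_EVENTS[e] if e >= 0 else "censored" for e in first_event
            ],
            "first_cycle": first_cycle,
        }
    )

    # post-event phase for non-fatal first events, censored at follow-up end
    rows = []
    for j, ev in enumerate(NONFATAL_EVENTS):
        idx = np.where(first_event == FIRST_EVENTS.index(ev))[0]
        if idx.size == 0:
            continue
        state = STATE_OF_EVENT[ev]
        death_eq = params.event_models[POST_DEATH_EQS[state]]
        sub_eqs = params.subsequent_event_models[state]
        sub_profiles = [profiles[i] for i in idx]
        d_const = death_eq.intercept + _profile_constants(sub_profiles, death_eq)
        d_bage = death_eq.betas.get("age", 0.0)
        s_const = {}
        s_bage = {}
        for sub, seq in sub_eqs.items():
            s_const[sub] = seq.intercept + _profile_constants(sub_profiles, seq)
            s_bage[sub] = seq.betas.get("age", 0.0)
        t0 = first_cycle[idx]
        alive = np.ones(idx.size, dtype=bool)
        for u in range(T):
            k = t0 + u
            act = alive & (k <= T - 1)
            if not act.any():
                break
            age_now = ages0[idx] + k
            flags = {}
            for sub, seq in sub_eqs.items():
                spl = (
                    float(seq.spline_value(float(u)))
                    if seq.spline_knots is not None
                    else 0.0
                )
                p_sub = ndtr(s_const[sub] + s_bage[sub] * age_now + spl)
                flags[sub] = (rng.random(idx.size) < p_sub) & act
            spl_d = (
                float(death_eq.spline_value(float(u)))
                if death_eq.spline_knots is not None
                else 0.0
            )
            p_d = ndtr(d_const + d_bage * age_now + spl_d)
            died = (rng.random(idx.size) < p_d) & act
            for pos in np.where(act)[0]:
                rows.append(
                    {
                        "person": int(idx[pos]),
                        "state": state,
                        "u": u,
                        "age": float(age_now[pos]),
                        **{sub: int(flags[sub][pos]) for sub in SUBSEQUENT_EVENTS},
                        "death": int(died[pos]),
                    }
                )
            alive = alive & ~died

    post_df = pd.DataFrame(
        rows,
        columns=["person", "state", "u", "age", *SUBSEQUENT_EVENTS, "death"],
    )
    return first_df, post_df


def recover_subsequent_equation(post_cycles: pd.DataFrame, state: str, event: str, truth_eq: EventEquation):
    """Probit recovery of one subsequent-event equation from person-years.

    Fits on the generating design (intercept, age, RCS in years since the
    first event with the truth's knots) and returns ``(estimates, ses,
    truth_values, fit)`` aligned as intercept, age beta, spline coefs.
    """
    from .utilities import fit_probit

    rows = post_cycles[post_cycles["state"] == state]
    X = np.column_stack(
        [
            np.ones(len(rows)),
            rows["age"].to_numpy(dtype=float),
            rcs_basis(rows["u"].to_numpy(dtype=float), truth_eq.spline_knots),
        ]
    )
    fit = fit_probit(X, rows[event].to_numpy(dtype=float))
    truth_values = np.array(
        [truth_eq.intercept, truth_eq.betas.get("age", 0.0), *truth_eq.spline_coefs]
    )
    return fit.params, fit.se, truth_values, fit


def make_cost_panel(
    n: int = 10000,
    truth=None,
    noise_sd: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Annual-cost panel (age, phase, event, years since event, cost) drawn
    from a known cost model plus Gaussian noise, for fit_cost_model recovery."""
    params = _unwrap(truth) if truth is not None else make_synthetic_params(0)[0]
    rng = np.random.default_rng(seed)
    cm = params.cost_model
    n_pre = n // 2
    rows = []
    ages = rng.uniform(25, 100, size=n_pre)
    costs = cm.pre_event.raw_value(age=ages) + rng.normal(0, noise_sd, size=n_pre)
    for a, c in zip(ages, costs):
        rows.append(dict(age=a, phase="pre_event", event="", years_since_event=np.nan, cost=c))
    per_ev = (n - n_pre) // len(NONFATAL_EVENTS)
    for ev in NONFATAL_EVENTS:
        ages = rng.uniform(40, 100, size=per_ev)
        us = rng.uniform(0, 30, size=per_ev)
        costs = cm.post_event[ev].raw_value(age=ages, u=us) + rng.normal(
            0, noise_sd, size=per_ev
        )
        for a, u, c in zip(ages, us, costs):
            rows.append(
                dict(age=a, phase="post_event", event=ev, years_since_event=u, cost=c)
            )
    return pd.DataFrame(rows)


def make_cis_year(n: int = 200, seed: int = 0):
    """A synthetic year of continuous inpatient stays with the booked total.

    Returns ``(records, total)`` where ``total`` is the generator's own
    bookkeeping of episode costs plus hotelling excesses.
    """
    from .costs import CISRecord

    rng = np.random.default_rng(seed)
    records = []
    total = 0.0
    for _ in range(n):
        base = float(rng.uniform(500, 6000))
        trim = float(rng.integers(3, 21))
        los = float(rng.integers(1, 40))
        per_diem = float(rng.uniform(100, 400))
        records.append(
            CISRecord(
                principal_episode_cost=base,
                length_of_stay=los,
                trim_point=trim,
                per_diem=per_diem,
            )
        )
        total += base + per_diem * max(0.0, los - trim)
    return records, total


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


@dataclass
class MicrosimEstimate:
    """Monte-Carlo microsimulation means and standard errors."""

    n_paths: int
    means: dict
    ses: dict
    incidence: dict = field(default_factory=dict)


class _OracleTables:
    """Probability/utility/cost grids recomputed from the raw equations."""

    def __init__(self, profile: RiskProfile, params: ParameterSet, config: RunConfig):
        from .profiles import term_value

        T = config.horizon
        self.T = T
        age0 = float(profile.age)
        ages_pts = age0 + np.arange(T + 1, dtype=float)

        def lp_curve(eq: EventEquation, spline_args: np.ndarray, ages: np.ndarray):
            const = eq.intercept + sum(
                b * term_value(profile, t)
                for t, b in eq.betas.items()
                if t != "age"
            )
            b_age = eq.betas.get("age", 0.0)
            spl = (
                rcs_value(spline_args, eq.spline_knots, eq.spline_coefs)
                if eq.spline_knots is not None
                else np.zeros_like(spline_args)
            )
            return const + b_age * ages + spl

        cycles = np.arange(T, dtype=float)
        self.q = np.stack(
            [
                ndtr(lp_curve(params.event_models[ev], cycles, ages_pts[:T]))
                for ev in FIRST_EVENTS
            ]
        )

        bands = age_band_index(ages_pts)
        six = SEXES.index(profile.sex)
        self.bg = params.utility_table.values[six, bands, profile.fifth - 1]

        cm = params.cost_model
        self.pre_cost = np.maximum(cm.pre_event.raw_value(age=ages_pts[:T]), 0.0)

        self.p_death = {}
        self.p_sub = {}
        self.delta_first = {}
        self.post_cost = {}
        self.deltas = params.decrements.as_vector()
        for ev in NONFATAL_EVENTS:
            state = STATE_OF_EVENT[ev]
            death_eq = params.event_models[POST_DEATH_EQS[state]]
            # grids over (t0, u); only cells with t0 + u <= T are used
            pd_grid = np.zeros((T, T + 1))
            ps_grid = np.zeros((len(SUBSEQUENT_EVENTS), T, T + 1))
            pc_grid = np.zeros((T, T))
            for t0 in range(T):
                u = np.arange(T + 1 - t0, dtype=float)
                ages = age0 + t0 + u
                pd_grid[t0, : u.size] = ndtr(lp_curve(death_eq, u, ages))
                for jj, sub in enumerate(SUBSEQUENT_EVENTS):
                    seq = params.subsequent_event_models[state][sub]
                    ps_grid[jj, t0, : u.size] = ndtr(lp_curve(seq, u, ages))
                uu = u[: T - t0]
                pc_grid[t0, : uu.size] = np.maximum(
                    cm.post_event[ev].raw_value(age=age0 + t0 + uu, u=uu), 0.0
                )
            self.p_death[ev] = pd_grid
            self.p_sub[ev] = ps_grid
            self.post_cost[ev] = pc_grid
            self.delta_first[ev] = params.decrements.first_event_decrement(ev)


def microsim_oracle(
    profile: RiskProfile,
    params: ParameterSet,
    config: RunConfig | None = None,
    n_paths: int = 200000,
    seed: int = 0,
) -> MicrosimEstimate:
    """Monte-Carlo microsimulation of individual paths.

    First events, post-event deaths and subsequent-event indicators are
    realised as Bernoulli draws cycle by cycle; life years, quality-weighted
    years and survival-conditioned costs are accumulated per path with the
    same mid-cycle conventions as the analytic engine, then averaged.
    """
    config = config or RunConfig()
    if n_paths < 1:
        raise ValidationError("n_paths must be >= 1")
    tab = _OracleTables(profile, params, config)
    T = tab.T
    rng = np.random.default_rng(seed)
    df_o = (1.0 + config.outcome_rate) ** -(np.arange(T) + 0.5)
    df_c = (1.0 + config.cost_rate) ** -(np.arange(T) + 0.5)

    n = n_paths
    first_event = np.full(n, -1)
    t0 = np.full(n, T - 1)
    active = np.ones(n, dtype=bool)
    cum_q = np.cumsum(tab.q, axis=0)  # (4, T)
    for t in range(T):
        if not active.any():
            break
        r = rng.random(n)
        ev = (r[:, None] >= cum_q[:, t][None, :]).sum(axis=1)
        hit = active & (ev < 4)
        first_event[hit] = ev[hit]
        t0[hit] = t
        active[hit] = False
    # residual survivors are booked as fatal non-CVD death at the last cycle
    forced = first_event < 0
    first_event[forced] = FIRST_EVENTS.index("fatal_non_cvd")

    le_u = np.zeros(n)
    le_d = np.zeros(n)
    qa_u = np.zeros(n)
    qa_d = np.zeros(n)
    co_u = np.zeros(n)
    co_d = np.zeros(n)

    # pre-event cycles 0..t0-1: certain survival at background utility
    cum_le_d = np.concatenate([[0.0], np.cumsum(df_o)])
    bg_occ = 0.5 * (tab.bg[:-1] + tab.bg[1:])
    cum_qa_u = np.concatenate([[0.0], np.cumsum(bg_occ)])
    cum_qa_d = np.concatenate([[0.0], np.cumsum(bg_occ * df_o)])
    cum_co_u = np.concatenate([[0.0], np.cumsum(tab.pre_cost)])
    cum_co_d = np.concatenate([[0.0], np.cumsum(tab.pre_cost * df_c)])
    le_u += t0
    le_d += cum_le_d[t0]
    qa_u += cum_qa_u[t0]
    qa_d += cum_qa_d[t0]
    co_u += cum_co_u[t0]
    co_d += cum_co_d[t0]

    # fatal first events: die mid-cycle t0 at background utility
    for ev in FATAL_EVENTS:
        mask = first_event == FIRST_EVENTS.index(ev)
        k = t0[mask]
        le_u[mask] += 0.5
        le_d[mask] += 0.5 * df_o[k]
        qa_u[mask] += 0.5 * tab.bg[k]
        qa_d[mask] += 0.5 * tab.bg[k] * df_o[k]
        co_u[mask] += 0.5 * tab.pre_cost[k]
        co_d[mask] += 0.5 * tab.pre_cost[k] * df_c[k]

    # non-fatal first events: realised post-event path
    for ev in NONFATAL_EVENTS:
        idx = np.where(first_event == FIRST_EVENTS.index(ev))[0]
        if idx.size == 0:
            continue
        t0e = t0[idx]
        p_death = tab.p_death[ev]
        p_sub = tab.p_sub[ev]
        post_cost = tab.post_cost[ev]
        d1 = tab.delta_first[ev]

        def realized_w(u_val, alive_mask):
            """Utility at point t0+u for currently alive paths."""
            w = tab.bg[np.minimum(t0e + u_val, T)] - d1
            for jj in range(len(SUBSEQUENT_EVENTS)):
                pj = p_sub[jj, t0e, u_val]
                flag = rng.random(idx.size) < pj
                w = w - flag * tab.deltas[jj]
            return np.where(alive_mask, np.maximum(w, 0.0), 0.0)

        alive = np.ones(idx.size, dtype=bool)
        wprev = realized_w(0, alive)
        # the pre-event prefix credited cycle t0-1 with background utility at
        # both endpoints; its right endpoint is the (lower) post-event utility
        has_pre = t0e >= 1
        adj = np.where(has_pre, 0.5 * (tab.bg[t0e] - wprev), 0.0)
        qa_u[idx] -= adj
        qa_d[idx] -= adj * df_o[np.maximum(t0e - 1, 0)]
        for u in range(T):
            k = t0e + u
            act = alive & (k <= T - 1)
            if not act.any():
                break
            died = (rng.random(idx.size) < p_death[t0e, u]) & act
            v_next = act & ~died
            wnext = realized_w(u + 1, v_next)
            occ = np.where(act, 0.5 * (1.0 + v_next), 0.0)
            kk = np.minimum(k, T - 1)
            le_u[idx] += occ
            le_d[idx] += occ * df_o[kk]
            qa_contrib = np.where(act, 0.5 * (wprev + wnext), 0.0)
            qa_u[idx] += qa_contrib
            qa_d[idx] += qa_contrib * df_o[kk]
            c = post_cost[t0e, np.minimum(u, T - 1)]
            co_u[idx] += occ * c
            co_d[idx] += occ * c * df_c[kk]
            alive = v_next
            wprev = wnext

    quantities = {
        "life_expectancy": le_u,
        "qale": qa_u,
        "lifetime_cost": co_u,
        "life_expectancy_disc": le_d,
        "qale_disc": qa_d,
        "lifetime_cost_disc": co_d,
    }
    means = {k: float(v.mean()) for k, v in quantities.items()}
    ses = {k: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0 for k, v in quantities.items()}
    incidence = {
        ev: float((first_event == j).mean()) for j, ev in enumerate(FIRST_EVENTS)
    }
    return MicrosimEstimate(n_paths=n, means=means, ses=ses, incidence=incidence)


def enumerate_outcomes(profile: RiskProfile, params: ParameterSet, config: RunConfig | None = None) -> dict:
    """Exact expectation by exhaustive enumeration (small horizons).

    Enumerates every (first event, cycle) scenario and, for non-fatal
    events, every post-event death time.  The five subsequent-event
    indicators are independent of the death draws and enter the quality
    weight linearly, so each indicator's {0, 1} outcomes are summed exactly
    per post-event cycle.  Plain Python loops throughout; independent of
    the KMSA engine's vectorised tables.
    """
    config = config or RunConfig()
    tab = _OracleTables(profile, params, config)
    T = tab.T
    df_o = [(1.0 + config.outcome_rate) ** -(t + 0.5) for t in range(T)]
    df_c = [(1.0 + config.cost_rate) ** -(t + 0.5) for t in range(T)]

    def path_outcome(v, w, c):
        """Trapezoid life years / QALE and occupancy-weighted costs."""
        out = [0.0] * 6
        for t in range(T):
            occ = 0.5 * (v[t] + v[t + 1])
            qocc = 0.5 * (w[t] * v[t] + w[t + 1] * v[t + 1])
            out[0] += occ
            out[1] += qocc
            out[2] += occ * c[t]
            out[3] += occ * df_o[t]
            out[4] += qocc * df_o[t]
            out[5] += occ * c[t] * df_c[t]
        return out

    def expected_post_utility(ev, t0, u):
        """Two-point enumeration over each subsequent-event indicator."""
        w = tab.bg[t0 + u] - tab.delta_first[ev]
        for jj in range(len(SUBSEQUENT_EVENTS)):
            p = tab.p_sub[ev][jj, t0, u]
            contrib = 0.0
            for flag in (0, 1):
                prob = p if flag else 1.0 - p
                contrib += prob * flag * tab.deltas[jj]
            w -= contrib
        return max(0.0, w)

    totals = [0.0] * 6
    S = 1.0
    for t0 in range(T):
        for j, ev in enumerate(FIRST_EVENTS):
            p_scen = tab.q[j, t0] * S
            if ev == "fatal_non_cvd" and t0 == T - 1:
                # residual survival is forced into this scenario
                S_T = S
                for t in range(t0, T):
                    S_T *= 1.0 - sum(tab.q[jj, t] for jj in range(4))
                p_scen += S_T
            if p_scen == 0.0:
                continue
            if ev in FATAL_EVENTS:
                v = [1.0] * (t0 + 1) + [0.0] * (T - t0)
                w = list(tab.bg)
                c = list(tab.pre_cost)
                out = path_outcome(v, w, c)
                totals = [a + p_scen * b for a, b in zip(totals, out)]
            else:
                # enumerate the post-event death cycle (or horizon survival)
                w_post = [expected_post_utility(ev, t0, u) for u in range(T - t0 + 1)]
                c_base = [tab.pre_cost[t] for t in range(t0)] + [
                    tab.post_cost[ev][t0, u] for u in range(T - t0)
                ]
                surv = 1.0
                for death_u in range(T - t0 + 1):
                    if death_u < T - t0:
                        p_death_here = surv * tab.p_death[ev][t0, death_u]
                    else:
                        p_death_here = surv  # alive at the horizon
                    if p_death_here > 0.0:
                        v = (
                            [1.0] * (t0 + death_u + 1)
                            + [0.0] * (T - t0 - death_u)
                        )
                        w = list(tab.bg[:t0]) + w_post
                        out = path_outcome(v, w, c_base)
                        weight = p_scen * p_death_here
                        totals = [a + weight * b for a, b in zip(totals, out)]
                    if death_u < T - t0:
                        surv *= 1.0 - tab.p_death[ev][t0, death_u]
        S *= 1.0 - sum(tab.q[jj, t0] for jj in range(4))

    return {
        "life_expectancy": totals[0],
        "qale": totals[1],
        "lifetime_cost": totals[2],
        "life_expectancy_disc": totals[3],
        "qale_disc": totals[4],
        "lifetime_cost_disc": totals[5],
    }
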