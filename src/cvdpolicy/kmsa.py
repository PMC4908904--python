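"""The Kaplan-Meier sample average (KMSA) engine.

The type and timing of the first event define a scenario: 4 first events x
T cycles (400 with the default 100-year horizon).  Each scenario yields a
survival series, a quality-weighted survival series and an annual cost
series; life expectancy and QALE are areas under the (quality-adjusted)
survival curve by the trapezoid rule with half-cycle correction, and
lifetime costs weight each year's cost by mid-cycle survival occupancy.
Expected outcomes are the scenario-probability-weighted sums.

Timing conventions (see docs/methods.md): point k is the start of cycle k;
an event at cycle t occurs mid-cycle, so a fatal event at t credits t + 0.5
life years; post-event state applies from point t onwards; discounting is
at interval midpoints, (1 + r)^-(t + 0.5) for cycle t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .errors import ValidationError
from .events import (
    FirstEventDistribution,
    _profile_part_at,
    first_event_distribution,
)
from .parameters import (
    FATAL_EVENTS,
    FIRST_EVENTS,
    NONFATAL_EVENTS,
    POST_DEATH_EQS,
    STATE_OF_EVENT,
    SUBSEQUENT_EVENTS,
    ParameterSet,
    age_band_index,
)
from .profiles import RiskProfile, RunConfig, SEXES, as_path

__all__ = [
    "auc_half_cycle",
    "discount_factors",
    "scenario_outcome",
    "expected_outcomes",
    "risk_table",
    "ScenarioOutcome",
    "ExpectedOutcomes",
]


def auc_half_cycle(series) -> float:
    """Trapezoid area under a per-cycle series (one-year cycles).

    Equivalent to the half-cycle-corrected sum: events at cycle boundaries
    are credited half a cycle each side.
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("auc_half_cycle needs a series over at least one cycle")
    return float(np.sum((v[:-1] + v[1:]) * 0.5))


def discount_factors(T: int, rate: float, timing: str = "midcycle") -> np.ndarray:
    """Discount factor for each interval [t, t+1), evaluated at mid-cycle."""
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    if timing != "midcycle":
        raise ValidationError(f"unknown discount timing {timing!r}")
    return (1.0 + rate) ** -(np.arange(T) + 0.5)


@dataclass
class ScenarioOutcome:
    """Outcomes conditional on first event ``first_event`` at cycle ``cycle``."""

    first_event: str
    cycle: int
    life_years: float
    qale: float
    lifetime_cost: float
    life_years_disc: float
    qale_disc: float
    lifetime_cost_disc: float


@dataclass
class ExpectedOutcomes:
    """Scenario-probability-weighted life expectancy, QALE and lifetime cost."""

    life_expectancy: float
    qale: float
    lifetime_cost: float
    life_expectancy_disc: float
    qale_disc: float
    lifetime_cost_disc: float
    distribution: FirstEventDistribution = field(repr=False)
    scenario_grid: np.ndarray = field(repr=False)  # (4, T, 6) per-scenario outcomes
    expected_occupancy: np.ndarray = field(repr=False)  # (T,) mean alive-years per cycle
    config: RunConfig = field(repr=False)

    def scenario(self, event: str, cycle: int) -> ScenarioOutcome:
        i = FIRST_EVENTS.index(event)
        vals = self.scenario_grid[i, cycle]
        return ScenarioOutcome(event, cycle, *vals)


class _Tables:
    """Vectorised per-parameter-set building blocks shared by all scenarios."""

    def __init__(self, path, params: ParameterSet, config: RunConfig):
        self.path = path
        self.params = params
        self.config = config
        T = config.horizon
        self.T = T
        profile = path.base
        self.age0 = profile.age
        ages_pts = self.age0 + np.arange(T + 1, dtype=float)

        # background utility at every point (age band switches with integer age)
        if path.is_constant:
            fifths = np.full(T + 1, profile.fifth)
        else:
            fifths = np.array([path.at(k).fifth for k in range(T + 1)])
        bands = age_band_index(ages_pts)
        six = SEXES.index(profile.sex)
        self.bg = params.utility_table.values[six, bands, fifths - 1]

        self.df_o = discount_factors(T, config.outcome_rate)
        self.df_c = discount_factors(T, config.cost_rate)

        cm = params.cost_model
        self.pre_cost = np.maximum(cm.pre_event.raw_value(age=ages_pts[:T]), 0.0)

        # index matrix k = t0 + u over the (t0, u) grid, clipped at the horizon
        idx = np.add.outer(np.arange(T), np.arange(T + 1))
        idx_pts = np.minimum(idx, T)

        self.S_post: dict[str, list[np.ndarray]] = {}
        self.util_post: dict[str, np.ndarray] = {}
        self.post_cost: dict[str, np.ndarray] = {}

        u_pts = np.arange(T + 1, dtype=float)
        cycles_abs = np.arange(T + 1)
        for ev in NONFATAL_EVENTS:
            state = STATE_OF_EVENT[ev]
            # post-event death: conditional survival per event cycle t0
            eq = params.event_models[POST_DEATH_EQS[state]]
            A = _profile_part_at(eq, path, cycles_abs, ages_pts)
            B = eq.spline_value(u_pts) if eq.spline_knots is not None else np.zeros(T + 1)
            rows = []
            for t0 in range(T):
                n_post = T - t0
                death = ndtr(A[t0 : t0 + n_post] + B[:n_post])
                S = np.empty(n_post + 1)
                S[0] = 1.0
                np.cumprod(1.0 - death, out=S[1:])
                rows.append(S)
            self.S_post[ev] = rows

            # composite decrement over the (t0, u) grid
            comp = np.zeros((T, T + 1))
            for sub in SUBSEQUENT_EVENTS:
                seq = params.subsequent_event_models[state][sub]
                A_s = _profile_part_at(seq, path, cycles_abs, ages_pts)
                B_s = (
                    seq.spline_value(u_pts)
                    if seq.spline_knots is not None
                    else np.zeros(T + 1)
                )
                comp += params.decrements.delta(sub) * ndtr(A_s[idx_pts] + B_s[None, :])
            delta_first = params.decrements.first_event_decrement(ev)
            self.util_post[ev] = np.maximum(0.0, self.bg[idx_pts] - delta_first - comp)

            # post-event annual costs over the (t0, u) cycle grid
            from .splines import rcs_value

            curve = cm.post_event[ev]
            cost = np.full((T, T), curve.intercept)
            if curve.u_knots is not None:
                cost += rcs_value(u_pts[:T], curve.u_knots, curve.u_coefs)[None, :]
            if curve.age_knots is not None:
                age_part = rcs_value(ages_pts[:T], curve.age_knots, curve.age_coefs)
                cost += age_part[np.minimum(idx[:, :T], T - 1)]
            self.post_cost[ev] = np.maximum(cost, 0.0)

    # -- per-scenario series -------------------------------------------------

    def series(self, event: str, t0: int):
        """Survival points v(0..T), utility points w(0..T), costs c(0..T-1)."""
        T = self.T
        if event in FATAL_EVENTS:
            v = np.zeros(T + 1)
            v[: t0 + 1] = 1.0
            w = self.bg
            c = self.pre_cost
        else:
            v = np.concatenate([np.ones(t0), self.S_post[event][t0]])
            w = np.concatenate(
                [self.bg[:t0], self.util_post[event][t0, : T - t0 + 1]]
            )
            c = np.concatenate(
                [self.pre_cost[:t0], self.post_cost[event][t0, : T - t0]]
            )
        return v, w, c

    def outcome(self, event: str, t0: int) -> np.ndarray:
        v, w, c = self.series(event, t0)
        occ = 0.5 * (v[:-1] + v[1:])
        wq = w * v
        qocc = 0.5 * (wq[:-1] + wq[1:])
        cost_cycles = occ * c
        terminal = self.params.cost_model.terminal_cost
        if terminal:
            deaths = v[:-1] - v[1:]
            term_und = terminal * deaths.sum()
            term_dis = terminal * float(deaths @ self.df_c)
        else:
            term_und = term_dis = 0.0
        return np.array(
            [
                occ.sum(),
                qocc.sum(),
                cost_cycles.sum() + term_und,
                occ @ self.df_o,
                qocc @ self.df_o,
                cost_cycles @ self.df_c + term_dis,
            ]
        )


def scenario_outcome(
    profile_or_path,
    params: ParameterSet,
    event: str,
    cycle: int,
    config: RunConfig | None = None,
) -> ScenarioOutcome:
    """Life years, QALE and lifetime cost conditional on one scenario."""
    config = config or RunConfig()
    if event not in FIRST_EVENTS:
        raise ValidationError(f"unknown first event {event!r}")
    if not 0 <= cycle < config.horizon:
        raise ValidationError(f"cycle={cycle} outside [0, {config.horizon})")
    tables = _Tables(as_path(profile_or_path), params, config)
    return ScenarioOutcome(event, cycle, *tables.outcome(event, cycle))


def expected_outcomes(
    profile_or_path,
    params: ParameterSet,
    config: RunConfig | None = None,
) -> ExpectedOutcomes:
    """Expectation over the full 4 x horizon scenario grid.

    The probability of each scenario (from the cumulative incidence of the
    four first events) multiplies its outcome estimates; the products are
    summed.
    """
    config = config or RunConfig()
    path = as_path(profile_or_path)
    dist = first_event_distribution(path, params, config.horizon)
    tables = _Tables(path, params, config)
    T = config.horizon
    grid = np.zeros((len(FIRST_EVENTS), T, 6))
    totals = np.zeros(6)
    occupancy = np.zeros(T)
    for i, ev in enumerate(FIRST_EVENTS):
        for t0 in range(T):
            out = tables.outcome(ev, t0)
            grid[i, t0] = out
            p = dist.p[i, t0]
            if p > 0:
                totals += p * out
                v, _, _ = tables.series(ev, t0)
                occupancy += p * 0.5 * (v[:-1] + v[1:])
    return ExpectedOutcomes(
        life_expectancy=totals[0],
        qale=totals[1],
        lifetime_cost=totals[2],
        life_expectancy_disc=totals[3],
        qale_disc=totals[4],
        lifetime_cost_disc=totals[5],
        distribution=dist,
        scenario_grid=grid,
        expected_occupancy=occupancy,
        config=config,
    )


DEFAULT_RISK_TABLE_AXES = dict(
    sbp_values=(100, 120, 140, 160, 180),
    ratio_values=(3, 5, 7, 9, 10),
    ages=(40, 50, 60, 70),
    sexes=("male", "female"),
    cigarettes=(0, 20),
    simd_fifths=(1, 5),
)

#: representative SIMD scores for the least / most deprived fifths
DEFAULT_SIMD_SCORES = {1: 4.0, 2: 11.0, 3: 17.0, 4: 27.0, 5: 60.8}


def risk_table(
    params_by_sex: dict,
    config: RunConfig | None = None,
    *,
    family_history: float = 0.26,
    diabetes: float = 0.15,
    hdl_chol: float = 1.0,
    simd_scores: dict | None = None,
    age_anchored: bool = False,
    **axes,
):
    """QALE / life-expectancy / cost table over standard risk-table axes.

    Axes default to SBP {100..180} x total/HDL ratio {3..10} x age
    {40..70} x sex x smoking {0, 20 cigarettes/day} x SIMD fifth {1, 5}
    (800 cells).  Family history and diabetes enter as cohort expectations.
    ``age_anchored`` adds quality-adjusted expected age at death columns
    (current age + remaining QALE).
    """
    import pandas as pd

    config = config or RunConfig()
    spec = dict(DEFAULT_RISK_TABLE_AXES)
    spec.update(axes)
    simd_scores = simd_scores or DEFAULT_SIMD_SCORES
    rows = []
    for sex in spec["sexes"]:
        params = params_by_sex[sex] if isinstance(params_by_sex, dict) else params_by_sex
        for fifth in spec["simd_fifths"]:
            for cigs in spec["cigarettes"]:
                for age in spec["ages"]:
                    for sbp in spec["sbp_values"]:
                        for ratio in spec["ratio_values"]:
                            profile = RiskProfile(
                                age=age,
                                sex=sex,
                                simd=simd_scores[fifth],
                                family_history=family_history,
                                diabetes=diabetes,
                                sbp=sbp,
                                total_chol=ratio * hdl_chol,
                                hdl_chol=hdl_chol,
                                cigarettes_per_day=cigs,
                            )
                            res = expected_outcomes(profile, params, config)
                            row = dict(
                                sex=sex,
                                simd_fifth=fifth,
                                cigarettes_per_day=cigs,
                                age=age,
                                sbp=sbp,
                                chol_ratio=ratio,
                                life_expectancy=res.life_expectancy,
                                qale=res.qale,
                                lifetime_cost=res.lifetime_cost,
                                qale_disc=res.qale_disc,
                                lifetime_cost_disc=res.lifetime_cost_disc,
                            )
                            if age_anchored:
                                row["qale_age_anchored"] = age + res.qale
                                row["qale_disc_age_anchored"] = age + res.qale_disc
                            rows.append(row)
    return pd.DataFrame(rows)
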