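"""Discrete-time competing-risk machinery.

Each annual cycle, an event-free individual faces cause-specific conditional
probabilities for the four first events (non-fatal CHD, non-fatal CBVD,
fatal CVD, fatal non-CVD), applied simultaneously with no within-cycle
ordering.  Event-free survival is the product of the per-cycle complements,
and the unconditional probability of scenario (event e at cycle t) is
q_e(t) * S(t).  One first event must occur within the horizon: any residual
survival at the final cycle is booked as fatal non-CVD death there, so the
scenario probabilities sum to one exactly.

After a first non-fatal event the individual transits through a post-event
state with its own annual death probability, driven by years since the event
(spline argument) and attained age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .errors import EngineError, ValidationError
from .parameters import (
    FIRST_EVENTS,
    NONFATAL_EVENTS,
    POST_DEATH_EQS,
    RESIDUAL_EVENT,
    STATE_OF_EVENT,
    EventEquation,
    ParameterSet,
)
from .profiles import ProfilePath, RiskProfile, as_path, term_value


def linear_predictor(
    profile: RiskProfile,
    eq: EventEquation,
    cycle: int,
    *,
    age: float | None = None,
    spline_arg: float | None = None,
) -> float:
    """Intercept + betas . risk factors + spline(time).

    ``age`` defaults to the profile's entry age advanced by ``cycle`` years;
    ``spline_arg`` defaults to the cycle index (first-event equations).
    Post-event equations pass years-since-event as the spline argument.
    """
    if cycle < 0:
        raise ValidationError(f"cycle must be >= 0, got {cycle}")
    if age is None:
        age = profile.age + cycle
    if spline_arg is None:
        spline_arg = cycle
    lp = eq.intercept
    for term, beta in eq.betas.items():
        lp += beta * term_value(profile, term, age=age)
    if eq.spline_knots is not None:
        lp += float(eq.spline_value(spline_arg))
    return float(lp)


def _profile_part(eq: EventEquation, path: ProfilePath, ages: np.ndarray) -> np.ndarray:
    """Intercept + betas . x over absolute cycles (no spline term).

    ``ages[k]`` is the attained age at cycle ``k``; the profile in force at
    cycle ``k`` supplies the other factors.
    """
    n = len(ages)
    out = np.full(n, eq.intercept, dtype=float)
    for term, beta in eq.betas.items():
        if term == "age":
            out += beta * ages
        elif path.is_constant:
            out += beta * term_value(path.base, term)
        else:
            out += beta * np.array(
                [term_value(path.at(k), term) for k in range(n)], dtype=float
            )
    return out


@dataclass
class FirstEventDistribution:
    """Per-cycle conditional probabilities, event-free survival and the
    unconditional scenario grid p(e, t)."""

    events: tuple
    horizon: int
    q: np.ndarray  # (4, T) conditional per-cycle probabilities
    S: np.ndarray  # (T+1,) event-free survival, S[0] = 1
    p: np.ndarray  # (4, T) unconditional scenario probabilities

    def total_incidence(self, event: str) -> float:
        """Total (lifetime) probability that ``event`` is the first event."""
        if event not in self.events:
            raise ValidationError(f"unknown first event {event!r}")
        return float(self.p[self.events.index(event)].sum())


def first_event_distribution(
    profile_or_path, params: ParameterSet, horizon: int = 100
) -> FirstEventDistribution:
    """Competing-risk distribution of the first event over the horizon.

    Residual event-free survival at the horizon is reassigned to fatal
    non-CVD death at the final cycle, so the 4 x horizon scenario grid has
    total probability exactly 1.
    """
    path = as_path(profile_or_path)
    if not (1 <= horizon <= 100):
        raise ValidationError(f"horizon={horizon} outside [1, 100]")
    cycles = np.arange(horizon)
    ages = path.base.age + cycles.astype(float)
    q = np.empty((len(FIRST_EVENTS), horizon))
    for i, ev in enumerate(FIRST_EVENTS):
        eq = params.event_models[ev]
        lp = _profile_part(eq, path, ages)
        if eq.spline_knots is not None:
            lp = lp + eq.spline_value(cycles.astype(float))
        q[i] = ndtr(lp)
    total = q.sum(axis=0)
    if np.any(total > 1.0):
        t_bad = int(np.argmax(total > 1.0))
        raise EngineError(
            f"cause-specific probabilities sum to {total[t_bad]:.4f} > 1 at cycle "
            f"{t_bad}; the engine does not renormalize - revise the event equations"
        )
    S = np.empty(horizon + 1)
    S[0] = 1.0
    np.cumprod(1.0 - total, out=S[1:])
    p = q * S[:horizon]
    p[FIRST_EVENTS.index(RESIDUAL_EVENT), horizon - 1] += S[horizon]
    return FirstEventDistribution(
        events=FIRST_EVENTS, horizon=horizon, q=q, S=S, p=p
    )


@dataclass
class PostEventSurvival:
    """Conditional survival after a first non-fatal event at cycle t0.

    ``S[u]`` is the probability of being alive u years after the event,
    S[0] = 1, truncated at the overall horizon (u runs 0..horizon - t0).
    """

    event_type: str
    event_cycle: int
    S: np.ndarray


def post_event_survival(
    profile_or_path,
    event_type: str,
    event_cycle: int,
    params: ParameterSet,
    horizon: int = 100,
) -> PostEventSurvival:
    """Survival curve from a first non-fatal event onwards.

    The post-event death equation's spline runs on years since the event;
    attained age keeps advancing one year per cycle.
    """
    if event_type not in NONFATAL_EVENTS:
        raise ValidationError(
            f"post-event survival requires a non-fatal first event, got {event_type!r}"
        )
    if not 0 <= event_cycle < horizon:
        raise ValidationError(
            f"event_cycle={event_cycle} outside [0, {horizon})"
        )
    path = as_path(profile_or_path)
    eq = params.event_models[POST_DEATH_EQS[STATE_OF_EVENT[event_type]]]
    n_post = horizon - event_cycle  # post-event cycles t0..horizon-1
    u = np.arange(n_post, dtype=float)
    ages = path.base.age + event_cycle + u
    lp = _profile_part_at(eq, path, event_cycle + np.arange(n_post), ages)
    if eq.spline_knots is not None:
        lp = lp + eq.spline_value(u)
    death = ndtr(lp)
    S = np.empty(n_post + 1)
    S[0] = 1.0
    np.cumprod(1.0 - death, out=S[1:])
    return PostEventSurvival(event_type=event_type, event_cycle=event_cycle, S=S)


def _profile_part_at(
    eq: EventEquation, path: ProfilePath, cycles: np.ndarray, ages: np.ndarray
) -> np.ndarray:
    """Like :func:`_profile_part` but for explicit absolute cycle indices."""
    out = np.full(len(cycles), eq.intercept, dtype=float)
    for term, beta in eq.betas.items():
        if term == "age":
            out += beta * ages
        elif path.is_constant:
            out += beta * term_value(path.base, term)
        else:
            out += beta * np.array(
                [term_value(path.at(int(k)), term) for k in cycles], dtype=float
            )
    return out
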