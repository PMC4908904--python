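"""Hospitalisation costing: CIS tariffs and annual cost curves.

A continuous inpatient stay (CIS) is costed as the principal episode cost
plus per-diem "hotelling" for days beyond the episode's trim point.  Annual
hospital costs enter the policy model through smooth curves: an age curve
before the first event, and per-first-event curves in years-since-event and
age afterwards (costs spike in the event year, fall as the survivor needs
less care, then rise again as comorbidities accumulate with age).  Curves
are OLS fits on restricted cubic spline bases; predictions extrapolate
linearly beyond the boundary knots and are floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError
from .parameters import NONFATAL_EVENTS, CostCurve, CostModel
from .splines import rcs_basis
from .utilities import fit_ols

PRE_EVENT = "pre_event"
POST_EVENT = "post_event"


@dataclass(frozen=True)
class CISRecord:
    """One continuous inpatient stay and its tariff inputs."""

    principal_episode_cost: float
    length_of_stay: float
    trim_point: float
    per_diem: float

    def __post_init__(self):
        for name in ("principal_episode_cost", "length_of_stay", "trim_point", "per_diem"):
            val = float(getattr(self, name))
            if val < 0:
                raise ValidationError(f"{name}={val} must be non-negative")
            object.__setattr__(self, name, val)


def cost_cis(record: CISRecord) -> float:
    """Geue method-1 CIS cost: episode cost + per-diem excess over trim point."""
    excess = max(0.0, record.length_of_stay - record.trim_point)
    return record.principal_episode_cost + record.per_diem * excess


def annual_cost(
    model: CostModel,
    phase: str,
    age: float,
    years_since_event: float | None = None,
    event: str | None = None,
) -> float:
    """Annual hospital cost for one cycle, floored at zero.

    ``phase`` is ``"pre_event"`` or ``"post_event"``; the post-event phase
    needs the first-event type and years since the event.
    """
    if phase == PRE_EVENT:
        value = model.pre_event.raw_value(age=age)
    elif phase == POST_EVENT:
        if years_since_event is None:
            raise ValidationError("post_event phase requires years_since_event")
        if event not in model.post_event:
            raise ValidationError(f"no post-event cost curve for event {event!r}")
        value = model.post_event[event].raw_value(age=age, u=years_since_event)
    else:
        raise ValidationError(f"unknown cost phase {phase!r}")
    return float(np.maximum(value, 0.0))


def fit_cost_model(
    panel: pd.DataFrame,
    age_knots=None,
    u_knots=None,
    terminal_cost: float = 0.0,
):
    """Fit the pre- and post-event annual cost curves by OLS on RCS bases.

    ``panel`` needs columns ``age``, ``phase`` (pre_event / post_event),
    ``event`` (first-event type, post rows only), ``years_since_event``
    (post rows only) and ``cost``.  Knots default to the conventional
    quantiles of the fitting data per phase.  Returns ``(CostModel, fits)``
    where ``fits`` maps curve name to its :class:`~cvdpolicy.utilities.OLSFit`
    (coefficient vcov included).
    """
    from .splines import default_knots

    panel = pd.DataFrame(panel)
    pre = panel[panel["phase"] == PRE_EVENT]
    if pre.empty:
        raise FitError("cost panel has no pre_event rows")
    fits = {}

    def knots_for(values, given):
        return np.asarray(given, dtype=float) if given is not None else default_knots(values)

    pre_age_knots = knots_for(pre["age"], age_knots)
    X = np.column_stack(
        [np.ones(len(pre)), rcs_basis(pre["age"].to_numpy(float), pre_age_knots)]
    )
    fit = fit_ols(X, pre["cost"].to_numpy(float))
    fits["pre_event"] = fit
    pre_curve = CostCurve(
        intercept=fit.params[0],
        age_knots=tuple(pre_age_knots),
        age_coefs=tuple(fit.params[1:]),
    )

    post_curves = {}
    for ev in NONFATAL_EVENTS:
        rows = panel[(panel["phase"] == POST_EVENT) & (panel["event"] == ev)]
        if rows.empty:
            raise FitError(f"cost panel has no post_event rows for event {ev!r}")
        ev_u_knots = knots_for(rows["years_since_event"], u_knots)
        ev_age_knots = knots_for(rows["age"], age_knots)
        X = np.column_stack(
            [
                np.ones(len(rows)),
                rcs_basis(rows["years_since_event"].to_numpy(float), ev_u_knots),
                rcs_basis(rows["age"].to_numpy(float), ev_age_knots),
            ]
        )
        fit = fit_ols(X, rows["cost"].to_numpy(float))
        fits[f"post_event.{ev}"] = fit
        n_u = len(ev_u_knots) - 1
        post_curves[ev] = CostCurve(
            intercept=fit.params[0],
            u_knots=tuple(ev_u_knots),
            u_coefs=tuple(fit.params[1 : 1 + n_u]),
            age_knots=tuple(ev_age_knots),
            age_coefs=tuple(fit.params[1 + n_u :]),
        )

    model = CostModel(
        pre_event=pre_curve, post_event=post_curves, terminal_cost=terminal_cost
    )
    return model, fits
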