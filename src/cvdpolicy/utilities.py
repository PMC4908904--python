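"""Quality adjustment: background utilities, decrements, subsequent events.

Three elements quality-adjust survival: (1) background morbidity, a utility
looked up by sex, age band and SIMD fifth; (2) the decrement of the first
non-fatal event (myocardial infarction for CHD, stroke for CBVD); (3) a
composite decrement for subsequent non-fatal CVD events -- the annual
probability of each of five event types (probit + restricted cubic spline in
years since the first event) times its decrement, summed.  The per-cycle
quality weight is the background utility minus both decrements, floored at
zero.

The module also houses the estimation routines used for parameter recovery
on synthetic survey and cohort data: OLS (utilities, decrements, cost
curves) and probit maximum likelihood (event equations), both delegating to
statsmodels behind a stable surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .errors import FitError, ValidationError
from .parameters import (
    POST_STATES,
    SUBSEQUENT_EVENTS,
    DecrementSet,
    ParameterSet,
    UtilityTable,
)
from .profiles import RiskProfile
from .events import linear_predictor


def background_utility(sex: str, age, simd_fifth: int, table: UtilityTable):
    """Population-norm utility for (sex, age, SIMD fifth).

    Constant within an age band; bands are half-open, so the score updates
    at the cycle where integer age enters a new band.
    """
    return table.lookup(sex, age, simd_fifth)


def subsequent_event_probability(
    profile: RiskProfile,
    state: str,
    event: str,
    years_since_first: float,
    params: ParameterSet,
    *,
    age: float | None = None,
) -> float:
    """Annual probability of one of the five subsequent non-fatal CVD events.

    ``age`` defaults to the profile's entry age advanced by
    ``years_since_first``; callers tracking the first-event cycle pass the
    attained age explicitly.  The linear predictor extrapolates linearly
    beyond the spline's boundary knots.
    """
    if state not in POST_STATES:
        raise ValidationError(f"unknown post-event state {state!r}")
    if event not in SUBSEQUENT_EVENTS:
        raise ValidationError(f"unknown subsequent event {event!r}")
    if years_since_first < 0:
        raise ValidationError("years_since_first must be >= 0")
    eq = params.subsequent_event_models[state][event]
    lp = linear_predictor(
        profile,
        eq,
        cycle=int(years_since_first),
        age=age if age is not None else profile.age + years_since_first,
        spline_arg=years_since_first,
    )
    return float(ndtr(lp))


def composite_decrement(probabilities, decrements: DecrementSet | np.ndarray) -> float:
    """Expected utility decrement from subsequent events: sum p_e * delta_e."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("subsequent-event probabilities must lie in [0, 1]")
    if isinstance(decrements, DecrementSet):
        d = decrements.as_vector()
    else:
        d = np.asarray(decrements, dtype=float)
    if p.shape != d.shape:
        raise ValidationError(
            f"probabilities {p.shape} and decrements {d.shape} must align"
        )
    return float(p @ d)


def cycle_utility(
    background: float,
    first_event_decrement: float | None,
    composite: float,
) -> float:
    """Quality weight for one cycle: background minus decrements, floored at 0.

    Pre-first-event cycles pass ``first_event_decrement=None`` and
    ``composite=0``.
    """
    dec = 0.0 if first_event_decrement is None else float(first_event_decrement)
    return max(0.0, float(background) - dec - float(composite))


# ---------------------------------------------------------------------------
# estimation routines (parameter recovery on synthetic data)
# ---------------------------------------------------------------------------


@dataclass
class OLSFit:
    params: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    sigma2: float
    resid: np.ndarray


@dataclass
class ProbitFit:
    params: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    converged: bool
    llf: float


def fit_ols(design, response) -> OLSFit:
    """Ordinary least squares with the usual coefficient vcov.

    Raises :class:`FitError` when the design is rank deficient.
    """
    import statsmodels.api as sm

    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError(f"design {X.shape} incompatible with response {y.shape}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient ({np.linalg.matrix_rank(X)} < {X.shape[1]})"
        )
    res = sm.OLS(y, X).fit()
    return OLSFit(
        params=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        se=np.asarray(res.bse),
        sigma2=float(res.scale),
        resid=np.asarray(res.resid),
    )


def fit_probit(design, outcomes, *, maxiter: int = 100, tol: float = 1e-8) -> ProbitFit:
    """Probit maximum likelihood via Newton scoring.

    Raises :class:`FitError` on complete separation or non-convergence.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = np.asarray(design, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise FitError("outcomes are all one class; probit is not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    model = sm.Probit(y, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"probit did not converge: complete separation suspected ({exc})")
    converged = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params)
    if not converged or not np.all(np.isfinite(params)):
        raise FitError(
            "probit did not converge: complete separation or ill-conditioned design"
        )
    # fitted probabilities of 0 or 1 at observed points also signal separation
    fitted = ndtr(X @ params)
    eps = np.finfo(float).tiny
    if np.any(fitted[y == 1] <= eps) or np.any(fitted[y == 0] >= 1 - eps):
        raise FitError("probit did not converge: complete separation detected")
    return ProbitFit(
        params=params,
        vcov=np.asarray(res.cov_params()),
        se=np.asarray(res.bse),
        converged=converged,
        llf=float(res.llf),
    )
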