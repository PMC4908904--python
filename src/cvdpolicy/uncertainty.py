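"""Uncertainty analysis: PSA, analysis of extremes, one-way sensitivity.

Probabilistic sensitivity analysis draws all coefficients at once from a
multivariate normal on the estimation scale, mean at the point estimates
and covariance from the parameter set's vcov, correlated via the Cholesky
factor.  Draws that violate structural invariants (utilities or decrements
out of range, cause probabilities exceeding one) are rejected, not clamped,
and the rejection rate is reported.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .econ import EconResult, Intervention, evaluate_intervention
from .errors import AnalysisError, CVDPolicyError, ValidationError
from .parameters import ParameterSet
from .profiles import RiskProfile, RunConfig

__all__ = [
    "cholesky_factor",
    "psa_draw",
    "run_psa",
    "analysis_of_extremes",
    "one_way_sa",
    "PSADraws",
    "CEAC",
]


def cholesky_factor(vcov: np.ndarray) -> np.ndarray:
    """Lower-triangular L with L L' = vcov (to 1e-10).

    A positive semi-definite (but not definite) matrix is handled by
    clipping eigenvalues at 1e-12 with a warning; asymmetric or indefinite
    input raises.
    """
    vcov = np.asarray(vcov, dtype=float)
    if vcov.ndim != 2 or vcov.shape[0] != vcov.shape[1]:
        raise ValidationError(f"vcov must be square, got {vcov.shape}")
    scale = max(1.0, float(np.abs(vcov).max()))
    if not np.allclose(vcov, vcov.T, atol=1e-8 * scale):
        raise ValidationError("vcov must be symmetric")
    try:
        return np.linalg.cholesky(vcov)
    except np.linalg.LinAlgError:
        pass
    eigvals, eigvecs = np.linalg.eigh(vcov)
    if eigvals.min() < -1e-8 * scale:
        raise ValidationError(
            f"vcov is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )
    _warnings.warn(
        "vcov is semi-definite; eigenvalues clipped at 1e-12 before factorization"
    )
    # null directions stay exactly null: clip tiny/negative eigenvalues to
    # zero and recover a lower-triangular factor of the clipped matrix via QR
    B = eigvecs * np.sqrt(np.where(eigvals < 1e-12, 0.0, eigvals))
    R = np.linalg.qr(B.T, mode="r")
    L = R.T
    # fix column signs so the diagonal is non-negative (conventional form)
    signs = np.where(np.diag(L) < 0, -1.0, 1.0)
    return L * signs[None, :]


def psa_draw(means: np.ndarray, L: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One correlated parameter draw: means + L z with z ~ N(0, I)."""
    means = np.asarray(means, dtype=float)
    L = np.asarray(L, dtype=float)
    if L.shape != (means.size, means.size):
        raise ValidationError(
            f"Cholesky factor {L.shape} does not conform with means {means.shape}"
        )
    return means + L @ rng.standard_normal(means.size)


@dataclass
class PSADraws:
    """Accepted PSA draws and their incremental outcomes."""

    n_draws: int
    seed: int
    parameters: np.ndarray  # (n_accepted, dim)
    delta_qale: np.ndarray
    delta_cost: np.ndarray
    n_rejected: int

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_draws


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""

    lambda_grid: np.ndarray
    probability: np.ndarray


def run_psa(
    profile: RiskProfile,
    intervention: Intervention,
    params: ParameterSet,
    config: RunConfig | None = None,
    *,
    n_draws: int = 1000,
    seed: int = 0,
    lambda_grid=None,
) -> tuple[PSADraws, CEAC]:
    """Probabilistic sensitivity analysis varying all parameters at once.

    Per accepted draw the parameter set is rebuilt and the intervention
    re-evaluated; CEAC(lambda) is the proportion of accepted draws with
    positive net monetary benefit lambda * dQALE - dcost.  Errors if more
    than half the draws are rejected.
    """
    config = config or RunConfig()
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if lambda_grid is None:
        lambda_grid = np.linspace(0.0, 50000.0, 26)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if params.vcov is None:
        raise ValidationError("ParameterSet has no vcov; PSA needs one")
    means = params.parameter_vector()
    L = cholesky_factor(np.asarray(params.vcov, dtype=float))
    rng = np.random.default_rng(seed)
    accepted, dq, dc = [], [], []
    n_rejected = 0
    for _ in range(n_draws):
        vec = psa_draw(means, L, rng)
        try:
            drawn = params.with_parameter_vector(vec)
            res = evaluate_intervention(profile, intervention, drawn, config)
        except CVDPolicyError:
            n_rejected += 1
            continue
        accepted.append(vec)
        dq.append(res.delta_qale_disc)
        dc.append(res.delta_cost_disc)
    if n_rejected > 0.5 * n_draws:
        raise AnalysisError(
            f"{n_rejected}/{n_draws} PSA draws rejected; review the "
            "parameterization (variances may be too large for the model's "
            "structural constraints)"
        )
    dq = np.asarray(dq)
    dc = np.asarray(dc)
    prob = np.array([(lam * dq - dc > 0).mean() for lam in lambda_grid])
    draws = PSADraws(
        n_draws=n_draws,
        seed=seed,
        parameters=np.asarray(accepted),
        delta_qale=dq,
        delta_cost=dc,
        n_rejected=n_rejected,
    )
    return draws, CEAC(lambda_grid=lambda_grid, probability=prob)


def _z(level: float) -> float:
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    return float(norm.ppf(0.5 + level / 2.0))


def analysis_of_extremes(
    profile: RiskProfile,
    intervention: Intervention,
    params: ParameterSet,
    config: RunConfig | None = None,
    *,
    level: float = 0.95,
    parameters=None,
) -> dict:
    """Expected, best-case and worst-case results at CI limits.

    Each parameter is set jointly to mean +/- z * SE, signed per parameter
    so that the joint move improves (best) or worsens (worst) the QALE gain;
    the direction is determined by numeric perturbation.  Restrict to a
    subset with ``parameters`` (names in the vcov ordering).
    """
    config = config or RunConfig()
    if params.vcov is None:
        raise ValidationError("ParameterSet has no vcov")
    means = params.parameter_vector()
    se = params.standard_errors()
    names = list(params.parameter_ordering())
    if parameters is None:
        indices = range(len(names))
    else:
        indices = []
        for p in parameters:
            if p not in names:
                raise ValidationError(f"unknown parameter {p!r}")
            indices.append(names.index(p))

    def dqale(vec):
        drawn = params.with_parameter_vector(vec)
        return evaluate_intervention(profile, intervention, drawn, config).delta_qale_disc

    base = dqale(means)
    signs = np.zeros(len(means))
    for i in indices:
        if se[i] == 0:
            continue
        vec = means.copy()
        vec[i] += 0.1 * se[i]
        signs[i] = np.sign(dqale(vec) - base) or 1.0

    z = _z(level)
    best_vec = means + z * signs * se
    worst_vec = means - z * signs * se

    def run(vec) -> EconResult:
        return evaluate_intervention(
            profile, intervention, params.with_parameter_vector(vec), config
        )

    return {"worst": run(worst_vec), "expected": run(means), "best": run(best_vec)}


def one_way_sa(
    profile: RiskProfile,
    intervention: Intervention,
    params: ParameterSet,
    config: RunConfig | None = None,
    *,
    parameters,
    level: float = 0.95,
):
    """Tornado table: ICER at mean +/- z * SE per parameter, others fixed.

    Returns a DataFrame sorted by descending |icer range|; parameters whose
    ICER is flagged (dominant/dominated/undefined) at either limit get NaN.
    """
    import pandas as pd

    config = config or RunConfig()
    if params.vcov is None:
        raise ValidationError("ParameterSet has no vcov")
    means = params.parameter_vector()
    se = params.standard_errors()
    names = list(params.parameter_ordering())
    z = _z(level)
    rows = []
    for p in parameters:
        if p not in names:
            raise ValidationError(f"unknown parameter {p!r} (not in vcov ordering)")
        i = names.index(p)
        icers = []
        for sign in (-1.0, 1.0):
            vec = means.copy()
            vec[i] += sign * z * se[i]
            res = evaluate_intervention(
                profile, intervention, params.with_parameter_vector(vec), config
            )
            icers.append(res.icer if res.icer is not None else np.nan)
        low, high = icers
        rows.append(
            dict(
                parameter=p,
                se=se[i],
                icer_low=low,
                icer_high=high,
                range=abs(high - low) if np.isfinite(low) and np.isfinite(high) else np.nan,
            )
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("range", ascending=False, na_position="last").reset_index(
        drop=True
    )
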