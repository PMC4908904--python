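"""Restricted cubic splines (Harrell's truncated-power construction).

A restricted cubic spline with knots k_1 < ... < k_K is a cubic spline
constrained to be linear for x <= k_1 and x >= k_K.  The basis used here is
the standard truncated-power form with the (k_K - k_1)^2 normalisation, so
all K-1 basis components are on roughly the scale of x itself.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

#: quantiles used for data-driven default knot placement (5 knots)
DEFAULT_KNOT_QUANTILES = (0.05, 0.275, 0.5, 0.725, 0.95)


def _check_knots(knots: np.ndarray) -> np.ndarray:
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValidationError(f"an RCS needs at least 3 knots, got {knots.size}")
    if np.any(np.diff(knots) <= 0):
        raise ValidationError(f"knots must be strictly ascending, got {knots.tolist()}")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Parameters
    ----------
    x : scalar or array
        Evaluation points.
    knots : sequence of K >= 3 strictly ascending reals.

    Returns
    -------
    ndarray with shape ``x.shape + (K - 1,)``.  The first component is ``x``
    itself (the linear term); components ``j = 2..K-1`` are the restricted
    truncated-power terms, each exactly linear outside [k_1, k_K].
    """
    knots = _check_knots(knots)
    x = np.asarray(x, dtype=float)
    K = knots.size
    norm = (knots[-1] - knots[0]) ** 2

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    comps = [x]
    kK, kK1 = knots[-1], knots[-2]
    for j in range(K - 2):
        kj = knots[j]
        term = (
            cube(x - kj)
            - cube(x - kK1) * (kK - kj) / (kK - kK1)
            + cube(x - kK) * (kK1 - kj) / (kK - kK1)
        )
        comps.append(term / norm)
    return np.stack(comps, axis=-1)


def rcs_value(x, knots, coefs) -> np.ndarray:
    """Spline contribution ``rcs_basis(x) . coefs`` (no intercept)."""
    coefs = np.asarray(coefs, dtype=float)
    basis = rcs_basis(x, knots)
    if coefs.shape[0] != basis.shape[-1]:
        raise ValidationError(
            f"spline has {basis.shape[-1]} basis components but {coefs.size} coefficients"
        )
    return basis @ coefs


def default_knots(data, n_knots: int = 5) -> np.ndarray:
    """Knots at the conventional quantiles of the fitting data."""
    data = np.asarray(data, dtype=float)
    if n_knots == 5:
        qs = DEFAULT_KNOT_QUANTILES
    else:
        qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(data, qs)
    if np.any(np.diff(knots) <= 0):
        raise ValidationError("data too discrete for the requested number of knots")
    return knots
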