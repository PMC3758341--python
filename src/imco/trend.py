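"""LOESS smoothing with a pointwise dispersion envelope.

Per-identity curves (IMco, species IM, exon means) are smoothed with
locally weighted polynomial regression: at each grid point x0 the
span-fraction nearest neighbours receive tricube kernel weights
scaled by the distance to the farthest included neighbour, optionally
multiplied by prior weights (the pair count behind each point), and a
degree-1 or degree-2 polynomial is fitted by weighted least squares.

The envelope is ``fitted +/- z * SE`` where SE is the standard error of
the local fit under the variance model Var(y_i) = sigma^2 / w_i — a
point estimated from w_i pairs is w_i times more precise — so the
envelope tightens as the counts behind the points grow.  No robustness
(bisquare) iterations are applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import ValidationError

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2
DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class SmoothedCurve:
    grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float
    degree: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if np.any(self.lower > self.fitted + 1e-12) or np.any(
            self.upper < self.fitted - 1e-12
        ):
            raise ValidationError("envelope must bracket the fitted values")


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel (1 - |u|^3)^3 on |u| < 1, else 0."""
    u = np.abs(np.asarray(u, dtype=float))
    w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
    return w


def _neighbourhood(x: np.ndarray, x0: float, span: float) -> np.ndarray:
    """Kernel weights of the span-fraction nearest neighbours of x0."""
    n = len(x)
    q = max(int(math.ceil(span * n)), 2)
    q = min(q, n)
    d = np.abs(x - x0)
    d_max = np.sort(d)[q - 1]
    if d_max == 0:
        return (d == 0).astype(float)
    return tricube(d / d_max)


def loess_smooth(
    xs,
    ys,
    weights=None,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    level: float = DEFAULT_LEVEL,
) -> SmoothedCurve:
    """Locally weighted polynomial smoothing over the observed x values.

    Parameters
    ----------
    xs, ys : array-like
        Points to smooth; the fit is evaluated at the sorted unique
        observed x values (no interpolation grid).
    weights : array-like of positive counts, optional
        Prior weights, typically the number of pairs behind each point;
        they multiply the kernel weights and sharpen the envelope.
    span : fraction of points in each local neighbourhood (0 < span <= 1).
    degree : local polynomial degree, 1 or 2.
    level : envelope confidence level (two-sided normal quantile).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValidationError("xs and ys must have equal length")
    if degree not in (1, 2):
        raise ValidationError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ValidationError("span must lie in (0, 1]")
    n = len(xs)
    if n < max(5, degree + 2):
        raise ValidationError(f"need at least {max(5, degree + 2)} points")
    if weights is None:
        w_prior = np.ones(n)
    else:
        w_prior = np.asarray(weights, dtype=float)
        if w_prior.shape != xs.shape or np.any(w_prior <= 0):
            raise ValidationError("weights must be positive and match xs")

    order = np.argsort(xs, kind="stable")
    xs, ys, w_prior = xs[order], ys[order], w_prior[order]
    grid = np.unique(xs)

    z = stats.norm.ppf(0.5 + level / 2.0)
    fitted = np.empty(len(grid))
    se = np.empty(len(grid))
    p = degree + 1
    for gi, x0 in enumerate(grid):
        k = _neighbourhood(xs, x0, span)
        w = k * w_prior
        active = w > 0
        xa, ya, wa = xs[active], ys[active], w[active]
        # centred polynomial basis for numerical stability
        basis = np.vander(xa - x0, p, increasing=True)
        sw = np.sqrt(wa)
        beta, *_ = np.linalg.lstsq(basis * sw[:, None], ya * sw, rcond=None)
        fitted[gi] = beta[0]
        resid = ya - basis @ beta
        sum_w = wa.sum()
        m = int(active.sum())
        if m <= p:
            se[gi] = 0.0  # exact interpolation, no residual information
            continue
        # per-observation variance scale under Var(y_i) = sigma^2 / w_i
        sigma2 = float(wa @ resid**2) / (sum_w * (1.0 - p / m))
        # fitted value is l'y with l = e1'(X'WX)^-1 X'W; Var = sigma2 * sum l_i^2 / w_prior_i
        xtwx = basis.T @ (basis * wa[:, None])
        l_vec = np.linalg.solve(xtwx, (basis * wa[:, None]).T)[0]
        var_fit = sigma2 * float(np.sum(l_vec**2 / w_prior[active]))
        se[gi] = math.sqrt(max(var_fit, 0.0))
    return SmoothedCurve(
        grid=grid,
        fitted=fitted,
        lower=fitted - z * se,
        upper=fitted + z * se,
        span=span,
        degree=degree,
    )
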