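"""Penalized-spline smoother with GCV-selected penalty.

A small Gaussian additive-model backbone: cubic B-spline basis with a
second-order difference penalty on the coefficients (a P-spline), penalty
strength chosen by generalized cross-validation on a log-spaced grid. The
effective degrees of freedom (edf) is the trace of the hat matrix, which is
how smoothness is reported for the photosynthesis-irradiance and thermal
performance fits.

With few distinct covariate values the basis dimension is clamped so the
design stays full rank; below 5 points the fit falls back to an ordinary
quadratic polynomial (edf = 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSmooth", "fit_penalized_spline"]

_LAMBDA_GRID = np.logspace(-8, 8, 81)


def _bspline_design(x: np.ndarray, xmin: float, xmax: float, nbasis: int, degree: int = 3):
    n_interior = nbasis - degree - 1
    if n_interior > 0:
        interior = np.quantile(np.unique(x), np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.concatenate(
        [np.repeat(xmin, degree + 1), interior, np.repeat(xmax, degree + 1)]
    )
    return knots, BSpline.design_matrix(np.clip(x, xmin, xmax), knots, degree).toarray()


@dataclass
class SplineSmooth:
    """A fitted smooth of y on x; call :meth:`predict` on new covariates.

    Predictions outside the fitted range are clamped to the boundary value
    (the smooth is never extrapolated).
    """

    kind: str  # "pspline" or "quadratic"
    xmin: float
    xmax: float
    coef: np.ndarray
    edf: float
    lambda_: float
    gcv: float
    rss: float
    n: int
    _knots: np.ndarray | None = None
    _degree: int = 3

    def predict(self, x) -> np.ndarray | float:
        scalar = np.isscalar(x)
        x = np.clip(np.atleast_1d(np.asarray(x, dtype=float)), self.xmin, self.xmax)
        if self.kind == "quadratic":
            out = np.polyval(self.coef, x)
        else:
            B = BSpline.design_matrix(x, self._knots, self._degree).toarray()
            out = B @ self.coef
        return float(out[0]) if scalar else out

    def loglik_gaussian(self) -> float:
        """Profile Gaussian log-likelihood at the MLE error variance."""
        sigma2 = max(self.rss / self.n, 1e-300)
        return -0.5 * self.n * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_penalized_spline(
    x,
    y,
    nbasis: int | None = None,
    degree: int = 3,
    lambdas: np.ndarray | None = None,
) -> SplineSmooth:
    """Fit a GCV-penalized cubic B-spline of ``y`` on ``x``.

    ``nbasis`` defaults to ``min(n_points - 1, 5)`` (clamped to at least
    ``degree + 1``); fewer than 5 points triggers the quadratic fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points to fit a smooth")
    xmin, xmax = float(x.min()), float(x.max())
    if xmin == xmax:
        raise ValueError("x values are all identical")

    n_unique = np.unique(x).size
    if n < 5 or n_unique < 5:
        deg = min(2, n_unique - 1)
        coef = np.polyfit(x, y, deg)
        if deg < 2:  # pad so polyval degree is stable
            coef = np.concatenate([np.zeros(2 - deg), coef])
        resid = y - np.polyval(coef, x)
        rss = float(resid @ resid)
        return SplineSmooth(
            kind="quadratic", xmin=xmin, xmax=xmax, coef=coef,
            edf=float(deg + 1), lambda_=0.0, gcv=np.nan, rss=rss, n=n,
        )

    if nbasis is None:
        nbasis = min(n - 1, 5)
    nbasis = int(max(nbasis, degree + 1))
    nbasis = min(nbasis, n_unique)

    knots, B = _bspline_design(x, xmin, xmax, nbasis, degree)
    D = np.diff(np.eye(nbasis), n=2, axis=0)
    BtB = B.T @ B
    Bty = B.T @ y
    P = D.T @ D
    lam_grid = _LAMBDA_GRID if lambdas is None else np.asarray(lambdas, dtype=float)

    best = None
    for lam in lam_grid:
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            Ainv_BtB = np.linalg.solve(A, BtB)
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(Ainv_BtB))
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0] - 1e-12 * max(abs(best[0]), 1.0):
            best = (gcv, lam, coef, edf, rss)
    if best is None:
        raise RuntimeError("penalized spline fit failed for all penalty values")
    gcv, lam, coef, edf, rss = best
    return SplineSmooth(
        kind="pspline", xmin=xmin, xmax=xmax, coef=coef,
        edf=edf, lambda_=float(lam), gcv=float(gcv), rss=rss, n=n,
        _knots=knots, _degree=degree,
    )
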