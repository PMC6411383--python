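"""Phylogenetic generalised least squares with ML Pagel's lambda.

The model for one response ``y`` over ``n`` species is

    y = X b + e,     e ~ MVN(0, sigma^2 * C(lambda))

where ``C(lambda)`` is the Brownian-motion tip covariance with off-diagonal
entries scaled by lambda.  For fixed lambda the GLS estimates are closed
form; lambda itself is profiled by maximum likelihood over [0, 1] with a
coarse grid followed by bounded scalar refinement.  Fits are scored with
the small-sample AICc so that models with different fixed-effect structures
can be compared on the same response.

Estimation is ML (not REML) throughout: AICc comparisons across different
fixed-effect structures are only valid under a common ML likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .treeio import PhyloCovariance, lambda_transform, stabilized_inverse_factor

__all__ = [
    "MODEL_NAMES",
    "DesignMatrix",
    "PGLSFit",
    "build_design",
    "gls_fit",
    "profile_lambda",
    "aicc",
]

# fixed model vocabulary: life history (AP), photosynthetic type (PT),
# additive, and interaction
MODEL_NAMES = ("AP×PT", "AP+PT", "PT", "AP")

# reference levels: annual (AP) and C3 (PT); the indicator columns flag
# perennial and C4 respectively
_AP_REF = "annual"
_PT_REF = "C3"


@dataclass
class DesignMatrix:
    model_name: str
    X: np.ndarray
    column_names: list[str]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class PGLSFit:
    """One model fitted to one response by PGLS."""

    model_name: str
    beta: np.ndarray
    sigma2: float
    lambda_hat: float
    logL: float
    k: int
    n: int
    aicc: float
    column_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "beta": dict(zip(self.column_names, np.round(self.beta, 10))),
            "sigma2": self.sigma2,
            "lambda": self.lambda_hat,
            "logL": self.logL,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
        }


def _indicator(series: pd.Series, ref: str, levels: tuple[str, str], factor: str) -> np.ndarray:
    vals = set(series.astype(str))
    if not vals <= set(levels):
        raise ValueError(f"{factor} levels must be within {levels}, got {sorted(vals)}")
    if len(vals) < 2:
        raise ValueError(f"factor {factor} has a single level ({vals.pop()}); design is rank-deficient")
    return (series.astype(str) != ref).to_numpy(dtype=float)


def build_design(groups: pd.DataFrame, model_name: str) -> DesignMatrix:
    """Treatment-coded design for one of the four factorial models.

    ``groups`` needs columns ``AP`` (annual/perennial) and ``PT`` (C3/C4);
    reference levels are annual and C3.  Column order is fixed as
    (intercept, AP, PT, AP:PT), subset to the requested model.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
    n = len(groups)
    cols = [np.ones(n)]
    names = ["intercept"]
    needs_ap = model_name in ("AP", "AP+PT", "AP×PT")
    needs_pt = model_name in ("PT", "AP+PT", "AP×PT")
    if needs_ap:
        ap = _indicator(groups["AP"], _AP_REF, ("annual", "perennial"), "AP")
        cols.append(ap)
        names.append("AP[perennial]")
    if needs_pt:
        pt = _indicator(groups["PT"], _PT_REF, ("C3", "C4"), "PT")
        cols.append(pt)
        names.append("PT[C4]")
    if model_name == "AP×PT":
        cols.append(ap * pt)
        names.append("AP:PT")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design for {model_name} is rank-deficient (empty factor cell)")
    return DesignMatrix(model_name, X, names)


def gls_fit(y: np.ndarray, X: np.ndarray | DesignMatrix, V: np.ndarray | PhyloCovariance):
    """Closed-form ML generalised least squares for fixed covariance V.

    Returns ``(beta, sigma2, logL)`` with

        beta   = (X' V^-1 X)^-1 X' V^-1 y
        sigma2 = r' V^-1 r / n              (ML, r = y - X beta)
        logL   = -n/2 [ln(2 pi sigma2) + 1] - 1/2 ln det V
    """
    if isinstance(X, DesignMatrix):
        X = X.X
    if isinstance(V, PhyloCovariance):
        V = V.C
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(y) != n or V.shape != (n, n):
        raise ValueError(f"dimension mismatch: y {len(y)}, X {X.shape}, V {V.shape}")

    L = stabilized_inverse_factor(V)
    # whiten: solve L z = . so that z'z = .' V^-1 .
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < p:
        raise np.linalg.LinAlgError("X' V^-1 X singular: design rank-deficient under V")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    sigma2 = float(r @ r) / n
    vy = float(np.var(y))
    if vy == 0 or sigma2 < 1e-12 * vy:
        raise FloatingPointError("degenerate fit: residual variance numerically zero")
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        raise FloatingPointError("degenerate fit: zero residual variance")
    logL = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdetV
    return beta, sigma2, float(logL)


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 < 1:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} < 1")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def profile_lambda(
    y: np.ndarray,
    X: np.ndarray | DesignMatrix,
    C: PhyloCovariance,
    *,
    n_grid: int = 21,
    tol: float = 1e-6,
    count_lambda_in_k: bool = True,
    model_name: str | None = None,
) -> PGLSFit:
    """Fit PGLS with Pagel's lambda estimated by maximum likelihood.

    A ``n_grid``-point grid on [0, 1] locates the basin; bounded scalar
    minimization refines to ``tol``.  Likelihood ties within 1e-8 resolve
    toward the smaller lambda (so a star tree, where lambda is
    unidentifiable, reports 0), and optima within 1e-4 of a bound snap to
    exactly 0 or 1.

    ``count_lambda_in_k`` controls whether lambda is counted as a fitted
    parameter in AICc (k = p + 2) or not (k = p + 1); differences in AICc
    across the four factorial models are unaffected because the same rule
    applies to every model.
    """
    if C.lambda_applied != "raw":
        raise ValueError("profile_lambda needs the raw (untransformed) covariance")
    Xmat = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    name = model_name or (X.model_name if isinstance(X, DesignMatrix) else "custom")
    colnames = X.column_names if isinstance(X, DesignMatrix) else [f"b{i}" for i in range(Xmat.shape[1])]
    n, p = Xmat.shape
    if n < p + 3:
        raise ValueError(f"too few species (n={n}) for p={p} coefficients plus sigma2 and lambda")

    def nll(lam: float) -> float:
        try:
            _, _, ll = gls_fit(y, Xmat, lambda_transform(C, lam))
        except (np.linalg.LinAlgError, FloatingPointError):
            return np.inf
        return -ll

    grid = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([nll(g) for g in grid])
    if not np.any(np.isfinite(vals)):
        raise FloatingPointError("likelihood non-finite across the whole lambda grid")
    # ties within 1e-8 resolve to the smallest lambda
    best = np.flatnonzero(vals <= np.nanmin(vals) + 1e-8)[0]
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    if hi > lo:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": tol})
        lam_hat, f_hat = float(res.x), float(res.fun)
    else:
        lam_hat, f_hat = float(grid[best]), float(vals[best])
    # prefer the grid point (and hence smaller lambda under ties)
    if vals[best] <= f_hat + 1e-8:
        lam_hat, f_hat = float(grid[best]), float(vals[best])
    if lam_hat < 1e-4:
        lam_hat = 0.0
    elif lam_hat > 1 - 1e-4:
        lam_hat = 1.0
    beta, sigma2, logL = gls_fit(y, Xmat, lambda_transform(C, lam_hat))
    k = p + 1 + (1 if count_lambda_in_k else 0)
    return PGLSFit(name, beta, sigma2, lam_hat, logL, k, n, aicc(logL, k, n), list(colnames))
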