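"""Phylogenetic principal component analysis (PPCA).

Ordinary PCA assumes independent observations; species data violate that
because close relatives covary.  PPCA replaces the arithmetic mean with the
GLS (phylogenetic) mean

    a = (1' C^-1 1)^-1  1' C^-1 X

and the sample covariance with the phylogenetically corrected form

    R = (X - 1a)' C^-1 (X - 1a) / (n - 1),

optionally rescaled to a correlation matrix, then eigen-decomposes R.
Species scores are computed in raw (uncorrected) trait space,
scores = (X - 1a) L, matching the convention in which species scores are
plotted directly.  On a star phylogeny C is proportional to the identity
and the whole procedure reduces to classical PCA.

The evolutionary covariance uses lambda = 1 (pure Brownian C) by default;
pass a transformed matrix for anything else.  Correlation mode is the
default because trait batteries typically span incommensurate units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeio import PhyloCovariance, stabilized_inverse_factor

__all__ = ["PPCAResult", "phylo_mean", "phylo_cov", "run_ppca"]


@dataclass
class PPCAResult:
    subset: str
    traits: list[str]
    taxa: list[str]
    phylo_mean: np.ndarray
    loadings: np.ndarray        # traits x PCs, unit-norm columns
    eigenvalues: np.ndarray     # nonincreasing
    percent_variance: np.ndarray
    scores: np.ndarray          # species x PCs

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.taxa, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.traits, columns=cols)

    def retained(self, threshold_pct: float = 20.0) -> list[int]:
        """0-based indices of PCs explaining at least ``threshold_pct``."""
        return [i for i, p in enumerate(self.percent_variance) if p >= threshold_pct]


def _as_matrix(Xdata) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(Xdata, pd.DataFrame):
        return Xdata.to_numpy(float), list(Xdata.columns), list(Xdata.index)
    X = np.atleast_2d(np.asarray(Xdata, float))
    return X, [f"x{i}" for i in range(X.shape[1])], [f"t{i}" for i in range(X.shape[0])]


def _cinv_apply(C: np.ndarray, M: np.ndarray) -> np.ndarray:
    L = stabilized_inverse_factor(C)
    return np.linalg.solve(L.T, np.linalg.solve(L, M))


def phylo_mean(Xdata, C: PhyloCovariance | np.ndarray) -> np.ndarray:
    """GLS estimate of the ancestral (root) mean of each trait."""
    X, _, _ = _as_matrix(Xdata)
    Cm = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    ones = np.ones(X.shape[0])
    ci1 = _cinv_apply(Cm, ones)
    return (ci1 @ X) / (ones @ ci1)


def phylo_cov(Xdata, C: PhyloCovariance | np.ndarray, mode: str = "correlation") -> np.ndarray:
    """Phylogenetically corrected trait covariance or correlation matrix."""
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"mode must be covariance|correlation, got {mode!r}")
    X, names, _ = _as_matrix(Xdata)
    Cm = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    n, m = X.shape
    if n < m + 1:
        warnings.warn(f"only {n} species for {m} traits; covariance is rank-deficient")
    a = phylo_mean(X, Cm)
    Xc = X - a
    R = Xc.T @ _cinv_apply(Cm, Xc) / (n - 1)
    if mode == "correlation":
        d = np.sqrt(np.diag(R))
        zero = [names[i] for i in np.flatnonzero(d <= 0)]
        if zero:
            raise ValueError(f"zero-variance traits in correlation mode: {zero}")
        R = R / np.outer(d, d)
    return R


def run_ppca(Xdata, C: PhyloCovariance | np.ndarray, mode: str = "correlation",
             subset: str = "all") -> PPCAResult:
    """Eigen-decompose the phylogenetic covariance/correlation of a trait set.

    PC signs are fixed so each loading column's largest-magnitude entry is
    positive; percent variance is eigenvalue / trace x 100.
    """
    X, names, taxa = _as_matrix(Xdata)
    Cm = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    a = phylo_mean(X, Cm)
    R = phylo_cov(X, Cm, mode)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign convention
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    Xc = X - a
    if mode == "correlation":
        d = np.sqrt(np.diag(phylo_cov(X, Cm, "covariance")))
        Xc = Xc / d
    scores = Xc @ evecs
    pct = evals / evals.sum() * 100.0
    return PPCAResult(subset, names, taxa, a, evecs, evals, pct, scores)
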