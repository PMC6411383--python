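"""AICc multimodel inference over the four factorial PGLS models.

For each response the four nested models — interaction (AP×PT), additive
(AP+PT), and the two single factors (PT, AP) — are fitted with their own
ML lambda, then compared through AICc differences:

    Delta_i = AICc_i - min_r AICc_r
    w_i     = exp(-Delta_i / 2) / sum_r exp(-Delta_r / 2)

``w_i`` is the model probability; the evidence ratio w_min/w_2 (largest
over second-largest weight) measures how decisively a single best model is
identified, and equals exp(Delta_2 / 2) identically.  Reports flag models
with Delta < 3.22 (evidence ratio vs. the best about 5.00) and weights
above 0.60, and stratify responses at evidence ratios of 5 and 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgls import MODEL_NAMES, PGLSFit, build_design, profile_lambda
from .treeio import PhyloCovariance

__all__ = [
    "ModelComparison",
    "akaike_weights",
    "evidence_ratio",
    "compare_models",
    "build_table",
    "DELTA_BOLD_THRESHOLD",
    "WEIGHT_BOLD_THRESHOLD",
]

DELTA_BOLD_THRESHOLD = 3.22   # Delta AICc below which a model is competitive
WEIGHT_BOLD_THRESHOLD = 0.60  # weight above which support is highlighted
ER_STRATA = (5.0, 2.5)

# tie rule for the best model: fewer parameters first, then this fixed order
_PARSIMONY_ORDER = ("AP", "PT", "AP+PT", "AP×PT")


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights (model probabilities) from AICc scores.

    Input may be raw AICc or already-referenced Delta values; weights are
    invariant to adding a constant, and Delta-referencing internally makes
    overflow impossible.
    """
    a = np.asarray(aicc_values, float)
    if a.ndim != 1 or a.size < 1 or not np.all(np.isfinite(a)):
        raise ValueError("aicc values must be a flat finite vector")
    delta = a - a.min()
    rel = np.exp(-0.5 * delta)
    return rel / rel.sum()


def evidence_ratio(weights) -> float:
    """Ratio of the largest to the second-largest Akaike weight."""
    w = np.sort(np.asarray(weights, float))[::-1]
    if w.size < 2:
        raise ValueError("evidence ratio needs at least two models")
    return float(w[0] / w[1])


@dataclass
class ModelComparison:
    """The four fitted models for one response, Table-2 style."""

    response: str
    fits: dict[str, PGLSFit]          # keyed by model name, fixed order
    delta_aicc: dict[str, float]
    weights: dict[str, float]
    evidence_ratio: float
    best_model: str
    second_model: str

    @property
    def lambda_best(self) -> float:
        return self.fits[self.best_model].lambda_hat

    def to_row(self) -> dict:
        row: dict = {"response": self.response}
        for m in MODEL_NAMES:
            row[f"dAICc_{m}"] = self.delta_aicc[m]
        for m in MODEL_NAMES:
            row[f"w_{m}"] = self.weights[m]
        row["evidence_ratio"] = self.evidence_ratio
        row["best_model"] = self.best_model
        row["lambda_best"] = self.lambda_best
        return row


def _pick_best(delta: dict[str, float]) -> tuple[str, str]:
    """Best and second-best model; ties (<1e-6) broken by parsimony."""
    order = sorted(
        MODEL_NAMES,
        key=lambda m: (round(delta[m] / 1e-6) * 1e-6, _PARSIMONY_ORDER.index(m)),
    )
    return order[0], order[1]


def compare_models(
    y: np.ndarray,
    groups: pd.DataFrame,
    C: PhyloCovariance,
    response: str = "trait",
    **fit_kwargs,
) -> ModelComparison:
    """Fit all four factorial models to one response and rank them.

    ``y`` must align row-wise with ``groups`` and with ``C.taxa``.  Each
    model gets its own ML lambda.  Errors from a single model fit propagate
    annotated with the model name.
    """
    fits: dict[str, PGLSFit] = {}
    for m in MODEL_NAMES:
        try:
            X = build_design(groups, m)
            fits[m] = profile_lambda(y, X, C, **fit_kwargs)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            raise type(exc)(f"model {m} on response {response!r}: {exc}") from exc
    aiccs = np.array([fits[m].aicc for m in MODEL_NAMES])
    delta = dict(zip(MODEL_NAMES, aiccs - aiccs.min()))
    w = dict(zip(MODEL_NAMES, akaike_weights(aiccs)))
    best, second = _pick_best(delta)
    er = evidence_ratio(list(w.values()))
    return ModelComparison(response, fits, delta, w, er, best, second)


def build_table(comparisons: list[ModelComparison]) -> pd.DataFrame:
    """Ranked model-comparison report (one response per row).

    Rows sort by descending evidence ratio; Delta AICc and the evidence
    ratio round to 2 dp, weights to 3 dp.  ``flag_dAICc_*`` marks models
    with Delta < 3.22, ``flag_w_*`` weights > 0.60, and ``stratum`` labels
    the evidence-ratio band (">5", ">2.5", "<=2.5").
    """
    if not comparisons:
        raise ValueError("no comparisons to tabulate")
    rows = []
    for c in sorted(comparisons, key=lambda c: -c.evidence_ratio):
        row = c.to_row()
        for m in MODEL_NAMES:
            row[f"dAICc_{m}"] = round(row[f"dAICc_{m}"], 2)
            row[f"w_{m}"] = round(row[f"w_{m}"], 3)
            row[f"flag_dAICc_{m}"] = c.delta_aicc[m] < DELTA_BOLD_THRESHOLD
            row[f"flag_w_{m}"] = c.weights[m] > WEIGHT_BOLD_THRESHOLD
        row["evidence_ratio"] = round(row["evidence_ratio"], 2)
        row["lambda_best"] = round(row["lambda_best"], 2)
        if c.evidence_ratio > ER_STRATA[0]:
            row["stratum"] = ">5"
        elif c.evidence_ratio > ER_STRATA[1]:
            row["stratum"] = ">2.5"
        else:
            row["stratum"] = "<=2.5"
        rows.append(row)
    return pd.DataFrame(rows)
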