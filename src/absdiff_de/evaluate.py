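"""Scoring of a test run against simulation truth.

Two summaries mirror the benchmark protocol: the empirical type-I error
rate — the fraction of genes with raw p below a cutoff on a dataset
known to contain no differential expression — and the ROC curve / AUC
of the p-value ranking against the true DE labels. The AUC is the
tie-corrected Mann-Whitney probability that a random DE gene receives a
smaller p-value than a random null gene, which equals the trapezoidal
area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["EvalReport", "type_i_error", "roc_auc"]


@dataclass
class EvalReport:
    """ROC points, AUC and/or type-I error for one or more runs."""

    auc: float
    roc_points: np.ndarray  # (n_thresholds, 2) of (FPR, TPR)
    type1_rate: float | None = None
    n_reps: int = 1


def type_i_error(pvalues: np.ndarray, cutoff: float = 0.05, is_de=None) -> float:
    """Fraction of genes with p < cutoff on a DE-free dataset.

    Raises if ``is_de`` is supplied and marks any gene as truly DE —
    the rate is only a type-I error under a global null.
    """
    p = np.asarray(pvalues, dtype=float)
    if is_de is not None and np.asarray(is_de).any():
        raise ValueError("type-I error requires a dataset without true DE genes")
    if p.size == 0:
        raise ValueError("no p-values")
    return float(np.mean(p < cutoff))


def roc_auc(pvalues: np.ndarray, is_de: np.ndarray) -> EvalReport:
    """ROC curve and tie-corrected AUC of the ascending-p ranking."""
    p = np.asarray(pvalues, dtype=float)
    truth = np.asarray(is_de, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("need at least one DE and one null gene")
    fpr, tpr, _ = roc_curve(truth, -p)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(auc=auc, roc_points=np.column_stack([fpr, tpr]))


def mean_auc(reports: list[EvalReport]) -> EvalReport:
    """Aggregate several single-run reports into a mean-AUC report."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return EvalReport(
        auc=float(np.mean([r.auc for r in reports])),
        roc_points=reports[0].roc_points,
        n_reps=len(reports),
    )
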