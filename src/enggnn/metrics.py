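"""Classification and feature-selection metrics, and Welch's t-test.

Classification: accuracy, ROC-AUC (trapezoidal over all score thresholds),
and F1 (harmonic mean of precision and recall), plus the raw confusion
counts.  Feature selection: the true-feature indicator from the simulator is
scored against importance pseudo-probabilities with ROC-AUC and PR-AUC
(average-precision estimator).  Model comparisons across replicates use
Welch's unequal-variance t-test with Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)

__all__ = [
    "MetricsReport",
    "classification_metrics",
    "feature_selection_metrics",
    "welch_compare",
]


@dataclass
class MetricsReport:
    accuracy: float
    roc_auc: float | None
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
            "f1": self.f1,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
        }


def classification_metrics(y_true, y_pred_labels, y_scores=None) -> MetricsReport:
    """Accuracy, ROC-AUC and F1 with confusion counts.

    ``y_scores`` are positive-class probabilities; ROC-AUC is ``None`` when
    scores are absent or ``y_true`` is single-class.  F1 is 0 when precision
    and recall are both undefined/zero.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred_labels must align")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    acc = (tp + tn) / y_true.size
    f1 = f1_score(y_true, y_pred, zero_division=0.0)
    auc = None
    if y_scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, np.asarray(y_scores)))
    return MetricsReport(
        accuracy=float(acc), roc_auc=auc, f1=float(f1),
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
    )


def feature_selection_metrics(true_mask, pseudo_probs) -> tuple[float, float]:
    """(ROC-AUC, PR-AUC) of an importance ranking against the true features.

    ``pseudo_probs`` are percentile-rank pseudo-probabilities; ``true_mask``
    is the simulator's informative-feature indicator.  Raises on a degenerate
    all-0/all-1 mask (callers report the cell as missing).
    """
    mask = np.asarray(true_mask)
    probs = np.asarray(pseudo_probs, dtype=np.float64)
    if mask.shape != probs.shape:
        raise ValueError("mask and scores must align")
    if mask.min() == mask.max():
        raise ValueError("true-feature mask is degenerate (single class)")
    return (
        float(roc_auc_score(mask, probs)),
        float(average_precision_score(mask, probs)),
    )


def welch_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Welch t-test between per-replicate metric vectors.

    Returns ``(t, p)``.  Two identical zero-variance samples give
    ``(0.0, 1.0)``; zero-variance samples with different means give
    ``(±inf, 0.0)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per model")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
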