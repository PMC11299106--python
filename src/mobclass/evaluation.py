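"""Multiclass evaluation: accuracy, Cohen's kappa, per-class metrics, ROC/AUC.

Overall agreement uses Cohen's kappa, kappa = (Po - Pe) / (1 - Pe), with
observed accuracy Po = trace / N and expected (chance) agreement
Pe = sum_i row_i * col_i / N^2.  Per class (one-vs-rest): balanced accuracy
(TPR + TNR) / 2, the harmonic mean of sensitivity and specificity
2*Sn*Sp/(Sn+Sp), and F1 = 2*precision*recall/(precision+recall).  ROC curves
are one-vs-rest per class with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "OverallMetrics",
    "ClassMetrics",
    "RocCurve",
    "confusion",
    "overall_metrics",
    "class_metrics",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.class_order)
        if c.shape != (n, n) or (c < 0).any():
            raise ValueError("counts must be a nonnegative n x n matrix")
        if c.sum() < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class OverallMetrics:
    accuracy: float  # observed agreement Po
    expected_accuracy: float  # chance agreement Pe
    kappa: float


@dataclass(frozen=True)
class ClassMetrics:
    tpr: float  # recall / sensitivity
    tnr: float  # specificity
    precision: float
    balanced_accuracy: float
    harmonic_mean: float
    f1: float
    degenerate: bool = False  # some denominator vanished; affected metrics are 0


@dataclass(frozen=True)
class RocCurve:
    points: np.ndarray  # (m, 2) array of (FPR, TPR), (0,0) .. (1,1)
    auc: float


def confusion(
    true_labels: list[str],
    predicted_labels: list[str],
    class_order: list[str] | tuple[str, ...],
) -> ConfusionMatrix:
    """Confusion matrix over a fixed class order."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    known = set(class_order)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def overall_metrics(cm: ConfusionMatrix) -> OverallMetrics:
    """Observed accuracy, chance agreement and Cohen's kappa."""
    c = np.asarray(cm.counts, dtype=float)
    n = c.sum()
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        raise ValueError("degenerate confusion matrix (Pe = 1): kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    return OverallMetrics(accuracy=float(po), expected_accuracy=float(pe), kappa=float(kappa))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def class_metrics(cm: ConfusionMatrix, target_class: str) -> ClassMetrics:
    """One-vs-rest metrics for a single class.

    When a denominator vanishes (class never true, never predicted, ...)
    the affected metrics are reported as 0 and ``degenerate`` is set.
    """
    if target_class not in cm.class_order:
        raise ValueError(f"unknown class {target_class!r}")
    i = cm.class_order.index(target_class)
    c = np.asarray(cm.counts, dtype=float)
    tp = c[i, i]
    fn = c[i].sum() - tp
    fp = c[:, i].sum() - tp
    tn = c.sum() - tp - fn - fp
    tpr, d1 = _safe_div(tp, tp + fn)
    tnr, d2 = _safe_div(tn, tn + fp)
    prec, d3 = _safe_div(tp, tp + fp)
    hm, d4 = _safe_div(2 * tpr * tnr, tpr + tnr)
    f1, d5 = _safe_div(2 * prec * tpr, prec + tpr)
    return ClassMetrics(
        tpr=tpr,
        tnr=tnr,
        precision=prec,
        balanced_accuracy=(tpr + tnr) / 2,
        harmonic_mean=hm,
        f1=f1,
        degenerate=d1 or d2 or d3 or d4 or d5,
    )


def roc_auc(scores, true_labels) -> RocCurve:
    """One-vs-rest ROC curve and trapezoidal AUC.

    ``true_labels`` is binary (1 = target class).  The threshold sweep runs
    over the unique scores; the AUC equals the Mann-Whitney probability that
    a random positive outscores a random negative (ties counted 1/2).
    """
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have the same shape")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined: need both positive and negative samples")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return RocCurve(points=points, auc=auc)
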