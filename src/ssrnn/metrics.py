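"""Confusion-matrix metrics: accuracy, precision, recall, F1.

Binary mode applies the textbook confusion-matrix definitions with class 1
as positive. Multi-class mode computes one-vs-rest per-class precision /
recall / F1 and aggregates them support-weighted by default — the
averaging whose recall coincides exactly with overall accuracy — or
unweighted ('macro'). Accuracy is always trace/total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics"]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mode: str = "weighted"

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predictions."""

    def __init__(self, counts):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == counts.astype(int)) or np.any(counts < 0):
                raise ValueError("counts must be nonnegative integers")
            counts = counts.astype(int)
        self.counts = counts

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __array__(self, dtype=None, copy=None):
        return np.array(self.counts, dtype=dtype)

    def __eq__(self, other):
        return np.array_equal(self.counts, np.asarray(other))


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """counts[r, c] = #{i : true_i = r, pred_i = c}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(cm)


def metrics(cm: ConfusionMatrix, mode: str = "weighted") -> MetricsReport:
    """Summarise a confusion matrix.

    mode 'binary' requires a 2x2 matrix and treats class 1 as positive;
    'weighted' / 'macro' aggregate one-vs-rest per-class scores. A class
    that is never predicted has undefined precision; it is scored 0 with a
    warning.
    """
    c = np.asarray(cm, dtype=float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(c) / total
    if mode == "binary":
        if c.shape != (2, 2):
            raise ValueError("binary mode requires a 2x2 confusion matrix")
        tn, fp, fn, tp = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
        precision = tp / (tp + fp) if tp + fp > 0 else _warn_zero("precision")
        recall = tp / (tp + fn) if tp + fn > 0 else _warn_zero("recall")
    elif mode in ("weighted", "macro"):
        col = c.sum(axis=0)
        row = c.sum(axis=1)
        diag = np.diag(c)
        if np.any((col == 0) & (row > 0)):
            warnings.warn(
                "some classes were never predicted; their precision is set to 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            prec_c = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
            rec_c = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
            f1_c = np.where(
                prec_c + rec_c > 0, 2 * prec_c * rec_c / (prec_c + rec_c), 0.0
            )
        if mode == "weighted":
            w = row / total
        else:
            w = np.full(c.shape[0], 1.0 / c.shape[0])
        precision = float(w @ prec_c)
        recall = float(w @ rec_c)
        return MetricsReport(float(accuracy), precision, recall, float(w @ f1_c), mode)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricsReport(float(accuracy), float(precision), float(recall), float(f1), mode)


def _warn_zero(name: str) -> float:
    warnings.warn(f"{name} undefined (zero denominator); scoring 0", stacklevel=3)
    return 0.0
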