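"""Performance measures: multiclass MCC, overall and per-class accuracy.

The multiclass Matthews correlation coefficient is computed from the N × K
one-hot indicator matrices of the true and predicted labels as
cov(X, Y) / sqrt(cov(X, X) · cov(Y, Y)), where cov(A, B) sums the per-class
column covariances.  This equals Gorodkin's R_K statistic; at K = 2 it
reduces to the classical binary MCC.  A zero variance term (e.g. a constant
prediction) yields 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class ConfusionMatrix:
    """K × K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K × K for K classes")
        if (self.counts < 0).any():
            raise ValueError("negative confusion count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _as_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(y_true).ravel()
    p = np.asarray(y_pred).ravel()
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} vs {p.shape[0]}")
    if t.size == 0:
        raise ValueError("empty label vectors")
    return t, p


def confusion_counts(y_true, y_pred, classes: Sequence[str] | None = None) -> ConfusionMatrix:
    t, p = _as_arrays(y_true, y_pred)
    if classes is None:
        classes = sorted(set(map(str, t)) | set(map(str, p)))
    classes = [str(c) for c in classes]
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(t, p):
        counts[index[str(a)], index[str(b)]] += 1
    return ConfusionMatrix(counts, list(classes))


def multiclass_mcc(y_true, y_pred) -> float:
    """Multiclass MCC in [−1, 1] from one-hot covariance sums; 0 when either
    variance term vanishes."""
    t, p = _as_arrays(y_true, y_pred)
    classes = sorted(set(map(str, t)) | set(map(str, p)))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    n = t.size
    X = np.zeros((n, k))
    Y = np.zeros((n, k))
    X[np.arange(n), [index[str(v)] for v in t]] = 1.0
    Y[np.arange(n), [index[str(v)] for v in p]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    denom = np.sqrt(cov_xx) * np.sqrt(cov_yy)
    if denom == 0.0:
        return 0.0
    return cov_xy / denom


def overall_accuracy(y_true, y_pred) -> float:
    """Fraction of exactly matching predictions."""
    t, p = _as_arrays(y_true, y_pred)
    return float(np.mean(t.astype(str) == p.astype(str)))


def per_class_accuracy(y_true, y_pred, classes: Sequence[str] | None = None) -> dict[str, float]:
    """Per-class recall: correct predictions of a class over its true count."""
    cm = confusion_counts(y_true, y_pred, classes)
    out: dict[str, float] = {}
    for i, c in enumerate(cm.classes):
        row = cm.counts[i].sum()
        if row == 0:
            continue
        out[c] = float(cm.counts[i, i] / row)
    return out


def metrics_report(y_true, y_pred, classes: Sequence[str] | None = None) -> dict:
    """Bundle MCC, ACC, per-class accuracies and the confusion matrix."""
    cm = confusion_counts(y_true, y_pred, classes)
    return {
        "mcc": multiclass_mcc(y_true, y_pred),
        "acc": overall_accuracy(y_true, y_pred),
        "per_class": per_class_accuracy(y_true, y_pred, cm.classes),
        "classes": cm.classes,
        "confusion_matrix": cm.counts.tolist(),
    }
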