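"""Target-domain evaluation metrics.

Accuracy is the fraction of target samples whose predicted label matches the
(held-out) true label.  Per-class precision, recall and F1 are derived from
one-vs-rest confusion counts; macro averages are unweighted means over
classes, micro averages pool the counts.  A zero denominator yields 0 and a
logged warning (degenerate classes are common in small target batches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "confusion_counts", "accuracy", "precision_recall_f1"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts from a single-label assignment."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_total: int

    def __post_init__(self):
        self.tp = np.asarray(self.tp, dtype=np.int64)
        self.fp = np.asarray(self.fp, dtype=np.int64)
        self.fn = np.asarray(self.fn, dtype=np.int64)
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if np.any(self.tp < 0) or np.any(self.fp < 0) or np.any(self.fn < 0):
            raise ValueError("confusion counts must be non-negative")
        if int(self.tp.sum()) > self.n_total:
            raise ValueError("sum of true positives exceeds the sample count")

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def _check_labels(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot evaluate on an empty label set")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return y_true, y_pred


def confusion_counts(y_true, y_pred, n_classes: int | None = None) -> ConfusionCounts:
    y_true, y_pred = _check_labels(y_true, y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for k in range(n_classes):
        tp[k] = int(np.sum((y_pred == k) & (y_true == k)))
        fp[k] = int(np.sum((y_pred == k) & (y_true != k)))
        fn[k] = int(np.sum((y_pred != k) & (y_true == k)))
    return ConfusionCounts(tp, fp, fn, n_total=len(y_true))


def accuracy(y_true, y_pred) -> float:
    """|{t : y_hat_t = y_t}| / |X_t|."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0", what)
        return 0.0
    return num / den


def precision_recall_f1(counts: ConfusionCounts) -> dict:
    """Per-class and macro/micro precision, recall and F1.

    Returns ``{"per_class": {k: {"precision", "recall", "f1"}},
    "macro_precision", "macro_recall", "macro_f1",
    "micro_precision", "micro_recall", "micro_f1"}``.
    """
    per_class = {}
    precisions, recalls, f1s = [], [], []
    for k in range(counts.n_classes):
        p = _safe_div(counts.tp[k], counts.tp[k] + counts.fp[k], f"precision[{k}]")
        r = _safe_div(counts.tp[k], counts.tp[k] + counts.fn[k], f"recall[{k}]")
        f1 = _safe_div(2.0 * p * r, p + r, f"f1[{k}]")
        per_class[k] = {"precision": p, "recall": r, "f1": f1}
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
    tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
    micro_p = _safe_div(tp, tp + fp, "micro precision")
    micro_r = _safe_div(tp, tp + fn, "micro recall")
    return {
        "per_class": per_class,
        "macro_precision": float(np.mean(precisions)),
        "macro_recall": float(np.mean(recalls)),
        "macro_f1": float(np.mean(f1s)),
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": _safe_div(2 * micro_p * micro_r, micro_p + micro_r, "micro f1"),
    }
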