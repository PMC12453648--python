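"""Per-class segmentation metrics: Precision, Recall, F1 and IoU.

Counts are micro-aggregated over pixels across the whole dataset
(confusions are summed, then metrics computed once), matching per-class
dataset-level reporting. A class absent from both prediction and
ground truth (TP=FP=FN=0) has no defined metrics; such rows are NA and
excluded from macro means. Background (class 0) appears in the table
but is excluded from the headline macro mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ConfusionCounts:
    """Per-class TP/FP/FN pixel tallies, additive across images."""

    def __init__(self, num_classes: int):
        self.num_classes = num_classes
        self.matrix = np.zeros((num_classes, num_classes), dtype=np.int64)  # [gt, pred]

    def update(self, pred: np.ndarray, gt: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
        k = self.num_classes
        if pred.max(initial=0) >= k or gt.max(initial=0) >= k:
            raise ValueError("label out of range")
        flat = gt.ravel() * k + pred.ravel()
        self.matrix += np.bincount(flat, minlength=k * k).reshape(k, k)
        return self

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        out = ConfusionCounts(self.num_classes)
        out.matrix = self.matrix + other.matrix
        return out


def accumulate_confusion(pred: np.ndarray, gt: np.ndarray, num_classes: int) -> ConfusionCounts:
    return ConfusionCounts(num_classes).update(pred, gt)


def _safe_div(a, b):
    return np.where(b > 0, a / np.where(b > 0, b, 1), np.nan)


def metrics_from_confusion(c: ConfusionCounts, class_names=None) -> pd.DataFrame:
    """Per-class metric table with NA for undefined rows.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    f1 = 2PR/(P+R), iou = TP/(TP+FP+FN).
    """
    tp, fp, fn = c.tp.astype(float), c.fp.astype(float), c.fn.astype(float)
    defined = (tp + fp + fn) > 0
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    # P=R=0 (tp=0 but fp,fn>0): harmonic mean is 0, not NA
    f1 = np.where(defined & (tp == 0), 0.0, f1)
    precision = np.where(defined & np.isnan(precision), 0.0, precision)
    recall = np.where(defined & np.isnan(recall), 0.0, recall)
    iou = np.where(defined, _safe_div(tp, tp + fp + fn), np.nan)
    precision = np.where(defined, precision, np.nan)
    recall = np.where(defined, recall, np.nan)
    f1 = np.where(defined, f1, np.nan)
    names = class_names or [f"class_{k}" for k in range(c.num_classes)]
    return pd.DataFrame(
        {"class_id": np.arange(c.num_classes), "class_name": names,
         "tp": c.tp, "fp": c.fp, "fn": c.fn,
         "precision": precision, "recall": recall, "f1": f1, "iou": iou}
    )


def macro_means(table: pd.DataFrame, include_background: bool = False) -> pd.Series:
    """Macro means over defined rows; background excluded by default."""
    rows = table if include_background else table[table["class_id"] != 0]
    return rows[["precision", "recall", "f1", "iou"]].mean(skipna=True)


def evaluate_masks(pairs, num_classes: int, class_names=None) -> pd.DataFrame:
    """Metric table over an iterable of (pred_mask, gt_mask) pairs."""
    c = ConfusionCounts(num_classes)
    n = 0
    for pred, gt in pairs:
        c.update(pred, gt)
        n += 1
    if n == 0:
        raise ValueError("empty dataset")
    return metrics_from_confusion(c, class_names)
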