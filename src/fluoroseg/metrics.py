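"""Evaluation metrics: confusion matrices, one-vs-rest rates, pixel accuracies.

Confusion matrices are oriented rows = actual, columns = predicted.
Reported rates are percentages rounded half-up to two decimals; raw values
are kept alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

RATE_COLUMNS = ("TPR", "TNR", "FPR", "FNR", "PPV", "NPV", "ACC")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (table convention; banker's rounding would differ)."""
    if np.isnan(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class BinaryMetrics:
    tp: int
    fn: int
    fp: int
    tn: int

    def _rate(self, num, den) -> float:
        return 100.0 * num / den if den else float("nan")

    @property
    def tpr(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def fpr(self) -> float:
        return self._rate(self.fp, self.tn + self.fp)

    @property
    def fnr(self) -> float:
        return self._rate(self.fn, self.tp + self.fn)

    @property
    def ppv(self) -> float:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def acc(self) -> float:
        return self._rate(self.tp + self.tn, self.tp + self.fn + self.fp + self.tn)

    def rounded(self) -> dict:
        """Counts plus 2-decimal percentage rates in the reporting column order."""
        raw = (self.tpr, self.tnr, self.fpr, self.fnr, self.ppv, self.npv, self.acc)
        out = {"TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn}
        out.update({k: round_half_up(v) for k, v in zip(RATE_COLUMNS, raw)})
        return out


def confusion_matrix(predicted, actual, classes) -> np.ndarray:
    """Count matrix with rows = actual class, columns = predicted class."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual label vectors differ in length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual.ravel(), predicted.ravel()):
        cm[index[a], index[p]] += 1
    return cm


def one_vs_rest_metrics(cm, class_index: int) -> BinaryMetrics:
    """Binary metrics for one class against the rest of a confusion matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = int(cm[class_index, class_index])
    fn = int(cm[class_index].sum() - tp)
    fp = int(cm[:, class_index].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    if tp + fn == 0 and tp + fp == 0:
        warnings.warn(f"class {class_index} absent from both rows and columns; "
                      "rates undefined", stacklevel=2)
    return BinaryMetrics(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics_table(cm, class_names) -> pd.DataFrame:
    """One-vs-rest report for every class, mirroring the reporting column order."""
    rows = [one_vs_rest_metrics(cm, i).rounded() for i in range(len(class_names))]
    return pd.DataFrame(rows, index=list(class_names))


def overall_accuracy(cm) -> float:
    """Percentage of the diagonal in the total count."""
    cm = np.asarray(cm)
    return 100.0 * np.trace(cm) / cm.sum()


def mask_accuracy(pred_mask, gt_mask) -> float:
    """Pixel-wise percentage agreement of two binary masks."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shapes differ")
    return 100.0 * float(np.mean(pred_mask == gt_mask))


def three_class_accuracy(pred_map3, gt_map3, gt_mask) -> float:
    """Accuracy over ground-truth tooth pixels for the three tooth classes.

    Restricting to the ground-truth mask makes the score independent of
    background-pixel predictions.
    """
    pred_map3 = np.asarray(pred_map3)
    gt_map3 = np.asarray(gt_map3)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if pred_map3.shape != gt_map3.shape or pred_map3.shape != gt_mask.shape:
        raise ValueError("shapes differ")
    from .labels import BACKGROUND3

    tooth = gt_mask & (gt_map3 != BACKGROUND3)
    if not tooth.any():
        raise ValueError("empty ground-truth tooth area")
    return 100.0 * float(np.mean(pred_map3[tooth] == gt_map3[tooth]))


def weighted_class_average(values, counts) -> float:
    """Count-weighted mean, e.g. per-class accuracies weighted by image counts."""
    values = np.asarray(values, dtype=np.float64)
    counts = np.asarray(counts, dtype=np.float64)
    if values.shape != counts.shape:
        raise ValueError("values and counts differ in length")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count")
    return float((values * counts).sum() / total)
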