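"""Regression and classification metrics for protein models.

Implemented directly from their defining formulas (R^2, MAE, MSE, RMSE;
accuracy, per-class precision/recall/F1 over the low/medium/high protein
classes) so they can be cross-checked against independent oracles in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import CLASS_NAMES

__all__ = [
    "RegressionMetrics",
    "ConfusionCounts",
    "ClassificationMetrics",
    "regression_metrics",
    "classification_metrics",
    "confusion_counts",
]


@dataclass(frozen=True)
class RegressionMetrics:
    r2: float
    mae: float
    mse: float
    rmse: float

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "mae": self.mae, "mse": self.mse, "rmse": self.rmse}


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> RegressionMetrics:
    """R^2, MAE, MSE and RMSE of predictions against observations."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant observations")
    mse = float(np.mean((y - yhat) ** 2))
    return RegressionMetrics(
        r2=1.0 - ss_res / ss_tot,
        mae=float(np.mean(np.abs(y - yhat))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/FP/FN/TN over the protein classes."""

    classes: tuple[str, ...]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray


def confusion_counts(labels, preds, classes=CLASS_NAMES) -> ConfusionCounts:
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    tp = np.zeros(len(classes), dtype=int)
    fp = np.zeros(len(classes), dtype=int)
    fn = np.zeros(len(classes), dtype=int)
    tn = np.zeros(len(classes), dtype=int)
    for i, cls in enumerate(classes):
        is_true = labels == cls
        is_pred = preds == cls
        tp[i] = int(np.sum(is_true & is_pred))
        fp[i] = int(np.sum(~is_true & is_pred))
        fn[i] = int(np.sum(is_true & ~is_pred))
        tn[i] = int(np.sum(~is_true & ~is_pred))
    return ConfusionCounts(tuple(classes), tp, fp, fn, tn)


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; defining it as 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(labels, preds, averaging: str = "macro",
                           classes=CLASS_NAMES) -> ClassificationMetrics:
    """Accuracy plus averaged precision/recall/F1.

    Macro averaging (the default) averages the per-class scores; micro
    averaging pools the counts, which for single-label multiclass makes
    precision = recall = accuracy.  Zero-denominator scores are defined as 0.
    """
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    if labels.size == 0 or labels.shape != preds.shape:
        raise ValueError("labels and preds must be equal-length and nonempty")
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")
    counts = confusion_counts(labels, preds, classes)
    accuracy = float(np.mean(labels == preds))
    if averaging == "micro":
        tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
        precision = _safe_div(tp, tp + fp, "micro precision")
        recall = _safe_div(tp, tp + fn, "micro recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, "micro F1")
    else:
        per_p, per_r = [], []
        for i in range(len(counts.classes)):
            per_p.append(_safe_div(counts.tp[i], counts.tp[i] + counts.fp[i],
                                   f"precision[{counts.classes[i]}]"))
            per_r.append(_safe_div(counts.tp[i], counts.tp[i] + counts.fn[i],
                                   f"recall[{counts.classes[i]}]"))
        precision = float(np.mean(per_p))
        recall = float(np.mean(per_r))
        # F1 stays the harmonic mean of the reported precision and recall
        f1 = _safe_div(2 * precision * recall, precision + recall, "macro F1")
    return ClassificationMetrics(accuracy, float(precision), float(recall),
                                 float(f1), averaging)
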