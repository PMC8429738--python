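"""Segmentation quality metrics: confusion matrix, ROC/PR curves, overlap.

Per-pixel, three classes (background, head, coin).  The single
sensitivity/specificity summaries are macro-averaged one-vs-rest values;
micro-averaging is available by flag.  Curve thresholds are taken at the
unique score values (ties grouped), so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

N_CLASSES = 3


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("confusion matrix must be 3x3 nonnegative counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CurvePoints:
    """Ordered curve with its trapezoidal area-under-curve."""

    x: np.ndarray
    y: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(x) < -1e-12):
            raise ValueError("curve x values must be nondecreasing")
        if not (0.0 - 1e-9 <= self.auc <= 1.0 + 1e-9):
            raise ValueError("AUC must lie in [0, 1]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


def confusion_matrix(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Pixel counts per (true class, predicted class) pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    idx = truth.ravel().astype(np.int64) * N_CLASSES + pred.ravel().astype(np.int64)
    counts = np.bincount(idx, minlength=N_CLASSES * N_CLASSES)
    return ConfusionMatrix(counts.reshape(N_CLASSES, N_CLASSES))


def classification_metrics(cm: ConfusionMatrix, average: str = "macro") -> dict:
    """Accuracy plus one-vs-rest sensitivity and specificity.

    Per class c: sensitivity = TP_c / P_c, specificity = TN_c / N_c.  A class
    absent from the ground truth yields NaN (undefined), not zero, and is
    excluded from the macro average.  ``average='micro'`` pools the
    one-vs-rest counts instead.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    p = c.sum(axis=1)
    pred_pos = c.sum(axis=0)
    fp = pred_pos - tp
    n = total - p
    tn = n - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(p > 0, tp / p, np.nan)
        spec = np.where(n > 0, tn / n, np.nan)
    if average == "macro":
        avg_sens = float(np.nanmean(sens))
        avg_spec = float(np.nanmean(spec))
    elif average == "micro":
        avg_sens = float(tp.sum() / p.sum())
        avg_spec = float(tn.sum() / n.sum())
    else:
        raise ValueError("average must be 'macro' or 'micro'")
    return {
        "accuracy": float(tp.sum() / total),
        "sensitivity": sens,
        "specificity": spec,
        "avg_sensitivity": avg_sens,
        "avg_specificity": avg_spec,
    }


def _threshold_counts(scores: np.ndarray, truth: np.ndarray):
    """Cumulative TP/FP at thresholds set by the unique descending scores."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    tp = np.cumsum(t)
    fp = np.cumsum(~t)
    # keep the last index of each tied score group
    last = np.nonzero(np.concatenate([s[1:] != s[:-1], [True]]))[0]
    return tp[last].astype(float), fp[last].astype(float), int(t.sum()), int((~t).sum())


def roc_points(scores: np.ndarray, truth: np.ndarray) -> CurvePoints:
    """ROC: TPR = TP/P against FPR = FP/N over all score thresholds."""
    tp, fp, npos, nneg = _threshold_counts(scores, truth)
    if npos == 0 or nneg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    tpr = np.concatenate([[0.0], tp / npos])
    fpr = np.concatenate([[0.0], fp / nneg])
    auc = float(np.trapezoid(tpr, fpr))
    return CurvePoints(x=fpr, y=tpr, auc=auc)


def pr_points(scores: np.ndarray, truth: np.ndarray) -> CurvePoints:
    """Precision TP/(TP+FP) against recall TP/P over all score thresholds."""
    tp, fp, npos, _ = _threshold_counts(scores, truth)
    if npos == 0:
        raise ValueError("precision-recall needs at least one positive")
    # stop once full recall is first reached: lower thresholds only add
    # false positives at the same recall
    cut = int(np.searchsorted(tp, tp[-1])) + 1
    tp, fp = tp[:cut], fp[:cut]
    recall = tp / npos
    precision = tp / np.maximum(tp + fp, 1.0)
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0] if len(precision) else 1.0], precision])
    auc = float(np.trapezoid(precision, recall))
    return CurvePoints(x=recall, y=precision, auc=auc)


def overlap_scores(pred: np.ndarray, truth: np.ndarray, cls: int) -> tuple[float, float]:
    """(IoU, F1) of one class region; both-empty is defined as (1, 1)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    a = pred == cls
    b = truth == cls
    union = int((a | b).sum())
    if union == 0:
        return 1.0, 1.0
    inter = int((a & b).sum())
    iou = inter / union
    f1 = 2.0 * inter / (a.sum() + b.sum())
    return float(iou), float(f1)


def evaluation_report(pred: np.ndarray, truth: np.ndarray,
                      probs: Optional[np.ndarray] = None) -> dict:
    """Bundle matrix, per-class metrics and (optionally) per-class curves."""
    cm = confusion_matrix(pred, truth)
    metrics = classification_metrics(cm)
    report = {
        "confusion_matrix": cm.counts.tolist(),
        "accuracy": metrics["accuracy"],
        "avg_sensitivity": metrics["avg_sensitivity"],
        "avg_specificity": metrics["avg_specificity"],
        "per_class": {},
    }
    for cls, name in enumerate(("background", "head", "coin")):
        iou, f1 = overlap_scores(pred, truth, cls)
        entry = {
            "sensitivity": float(metrics["sensitivity"][cls]),
            "specificity": float(metrics["specificity"][cls]),
            "iou": iou,
            "f1": f1,
        }
        if probs is not None:
            binary = (np.asarray(truth) == cls).ravel()
            if binary.any() and not binary.all():
                entry["roc_auc"] = roc_points(probs[..., cls].ravel(), binary).auc
                entry["pr_auc"] = pr_points(probs[..., cls].ravel(), binary).auc
        report["per_class"][name] = entry
    return report
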