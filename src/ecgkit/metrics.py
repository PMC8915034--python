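"""Evaluation metrics: PSNR for denoising, confusion-matrix metrics and
ROC/AUC for binary beat classification.

PSNR is ``10*log10((L-1)^2 / MSE)`` where ``L`` is the number of
possible intensity levels; for real-valued ECG, ``L - 1`` defaults to
the dynamic range (max - min) of the clean reference. Classification
metrics are the standard confusion-count ratios; metrics with a zero
denominator are reported as NaN sentinels rather than silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with positive class = 1 (abnormal beat)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics; NaN marks a 0/0 ratio."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    loss: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "loss": self.loss,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep: thresholds with their TPR/FPR, and trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def psnr(reference: np.ndarray, test: np.ndarray, levels: float | None = None) -> float:
    """Peak signal-to-noise ratio of ``test`` against a clean reference, in dB.

    ``levels`` is the number of intensity levels L; ``L - 1`` defaults
    to the reference's dynamic range. Identical signals return +inf.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if reference.size == 0:
        raise ValueError("signals must be non-empty")
    if levels is None:
        peak = float(reference.max() - reference.min())
        if peak <= 0:
            raise ValueError("reference has zero dynamic range; pass levels explicitly")
    else:
        if levels <= 1:
            raise ValueError(f"levels must be > 1, got {levels}")
        peak = float(levels) - 1.0
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def _check_binary(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return y.astype(int)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally binary confusion counts (positive class = 1)."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(c: ConfusionCounts, loss: float = math.nan) -> MetricsReport:
    """Accuracy, sensitivity/recall, specificity, precision and F1 from counts."""
    if c.total == 0:
        raise ValueError("cannot derive metrics from all-zero counts")
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    if math.isnan(sensitivity) or math.isnan(precision) or sensitivity + precision == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=sensitivity,
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=precision,
        recall=sensitivity,
        f1=f1,
        loss=loss,
    )


def binary_cross_entropy(y_true: np.ndarray, scores: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of predicted probabilities."""
    y = _check_binary(y_true, "y_true").astype(float)
    p = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def roc_curve(y_true: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC over a sweep of score thresholds, with trapezoidal AUC.

    Requires both classes present. TPR and FPR are each non-decreasing
    as the threshold decreases; the curve runs from (0,0) to (1,1).
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = skm.roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def evaluate_predictions(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> tuple[ConfusionCounts, MetricsReport, RocCurve]:
    """Full evaluation of probabilistic predictions at a decision threshold."""
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    counts = confusion(y_true, y_pred)
    report = classification_metrics(counts, loss=binary_cross_entropy(y_true, scores))
    roc = roc_curve(y_true, scores)
    return counts, report, roc
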