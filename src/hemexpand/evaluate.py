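"""Uncertainty and accuracy metrics for interval-valued volume predictions.

Covers 95% prediction-interval coverage and mean width (z fixed at 1.96
exactly, as the interval formulas are conventionally written), the rate of
noise-induced error change (RNH) for robustness under feature perturbation,
plain MSE/MAE, confusion-matrix rates and a rank-based ROC AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import rankdata

Z_95 = 1.96  # fixed z-multiplier of the nominal 95% interval


@dataclass(frozen=True)
class IntervalPrediction:
    """One predictive interval: mean, SD and the realized value, all in ml."""

    predicted_mean: float
    predicted_sd: float
    true_value: float

    def __post_init__(self):
        if not self.predicted_sd > 0:
            raise ValueError("predicted_sd must be > 0")


def _as_triplet(y_true, y_pred, sigma=None):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("inputs must be aligned and equal-length")
    if sigma is None:
        return y_true, y_pred
    sigma = np.asarray(sigma, dtype=float).ravel()
    if sigma.shape != y_true.shape:
        raise ValueError("inputs must be aligned and equal-length")
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be > 0")
    return y_true, y_pred, sigma


def coverage(y_true, y_pred, sigma, level: float = 0.95) -> float:
    """Fraction of true values inside [mean - 1.96 sd, mean + 1.96 sd].

    Only the 95% level is supported; the multiplier is fixed at 1.96.
    """
    if level != 0.95:
        raise ValueError("only the 95% level (z = 1.96) is supported")
    y_true, y_pred, sigma = _as_triplet(y_true, y_pred, sigma)
    half = Z_95 * sigma
    inside = (y_true >= y_pred - half) & (y_true <= y_pred + half)
    return float(inside.mean())


def width(sigma) -> float:
    """Mean 95% interval width, 2 * 1.96 * sigma averaged over predictions."""
    sigma = np.asarray(sigma, dtype=float).ravel()
    if sigma.size == 0:
        raise ValueError("empty input")
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be > 0")
    # multiply after averaging: identical in exact arithmetic, and keeps the
    # all-equal-sigma case at the verbatim 2 * 1.96 * sigma value
    return float(2.0 * Z_95 * np.mean(sigma))


@dataclass(frozen=True)
class RnhResult:
    value: float
    n_used: int
    n_excluded: int


def rnh(clean_pred, noisy_pred, y_true, eps: float = 1e-8) -> RnhResult:
    """Rate of noise-induced error change.

    Mean over i of |(e_i^noise) - e_i| / |e_i| with signed errors
    e = prediction - truth. Pairs whose baseline error magnitude is below
    ``eps`` are excluded (and counted) to avoid a zero denominator. Lower is
    more robust; identical predictions give exactly 0.
    """
    y_true, clean_pred = _as_triplet(y_true, clean_pred)
    y_true2, noisy_pred = _as_triplet(y_true, noisy_pred)
    clean_err = clean_pred - y_true
    noisy_err = noisy_pred - y_true
    keep = np.abs(clean_err) >= eps
    if not keep.any():
        raise ValueError("all pairs excluded: baseline errors below eps")
    ratio = np.abs(noisy_err[keep] - clean_err[keep]) / np.abs(clean_err[keep])
    return RnhResult(float(ratio.mean()), int(keep.sum()), int((~keep).sum()))


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        counts = (self.tn, self.fp, self.fn, self.tp)
        if any(c < 0 or int(c) != c for c in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionMatrix":
        labels = np.asarray(labels, dtype=bool).ravel()
        predicted = np.asarray(predicted, dtype=bool).ravel()
        if labels.shape != predicted.shape:
            raise ValueError("labels and predictions must be aligned")
        return cls(
            tn=int(np.sum(~labels & ~predicted)),
            fp=int(np.sum(~labels & predicted)),
            fn=int(np.sum(labels & ~predicted)),
            tp=int(np.sum(labels & predicted)),
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Rates from a confusion matrix; a metric with a zero denominator is None."""

    recall: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: float


def confusion_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Recall (sensitivity), specificity, precision and accuracy.

    Undefined rates (zero denominator) are reported as None, never as 0.
    """

    def rate(num, den):
        return num / den if den > 0 else None

    return ClassificationMetrics(
        recall=rate(cm.tp, cm.tp + cm.fn),
        specificity=rate(cm.tn, cm.tn + cm.fp),
        precision=rate(cm.tp, cm.tp + cm.fp),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via average ranks (ties counted half).

    Equivalent to the Mann-Whitney pair-counting statistic: the fraction of
    (positive, negative) pairs ranked concordantly, ties weighted 1/2.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be aligned and nonempty")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties at half weight
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def regression_errors(preds, truths) -> tuple[float, float]:
    """(MSE, MAE) of point predictions against realized values."""
    truths, preds = _as_triplet(truths, preds)
    err = preds - truths
    return float(np.mean(err**2)), float(np.mean(np.abs(err)))


@dataclass(frozen=True)
class EvaluationReport:
    """All metrics of one model run; rates in [0, 1], errors/width in ml."""

    mse: float
    mae: float
    coverage: float
    mean_width: float
    rnh: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: float
    auc: Optional[float]  # None when only one class is present

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        return cls(**json.loads(Path(path).read_text()))
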