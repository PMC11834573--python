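"""Evaluation metrics for affinity regression and binding-site classification.

Regression quality is reported as RMSE plus Pearson and Spearman
correlations between predicted and measured pK; site prediction as ROC-AUC,
the PR curve, and F1/accuracy at the 0.5 probability threshold.  The
formulas are implemented directly (the tie-free Spearman form is the
classical ``1 - 6*sum(d²)/(n(n²-1))``; ties fall back to Pearson on
mid-ranks, and the trapezoidal AUC handles tied scores by grouping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport", "rmse", "pearson", "spearman", "roc_curve", "roc_auc",
    "pr_curve", "f1_at_threshold", "accuracy_at_threshold", "evaluate_affinity",
    "evaluate_sites",
]


@dataclass
class MetricsReport:
    """Bundle of metric values with the sample count they were computed on."""

    rmse: float = float("nan")
    pearson: float = float("nan")
    spearman: float = float("nan")
    roc_auc: float = float("nan")
    f1: float = float("nan")
    n: int = 0
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("rmse", "pearson", "spearman", "roc_auc", "f1", "n")}
        if self.per_fold:
            d["per_fold"] = self.per_fold
        return d


def _check_lengths(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y, yhat = _check_lengths(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pearson(y, yhat) -> float:
    """Pearson correlation; NaN (with a warning) for constant input."""
    y, yhat = _check_lengths(y, yhat)
    if y.size < 2:
        raise ValueError("pearson needs at least 2 samples")
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = np.sqrt(np.sum(yc**2)) * np.sqrt(np.sum(pc**2))
    if denom == 0:
        warnings.warn("constant input to pearson; returning NaN")
        return float("nan")
    return float(np.sum(yc * pc) / denom)


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(y, yhat) -> float:
    """Spearman rank correlation.

    Tie-free inputs use the classical difference-of-ranks form; ties use
    Pearson on mid-ranks (the two agree exactly when there are no ties).
    """
    y, yhat = _check_lengths(y, yhat)
    n = y.size
    if n < 2:
        raise ValueError("spearman needs at least 2 samples")
    if len(np.unique(y)) == n and len(np.unique(yhat)) == n:
        d = _midranks(y) - _midranks(yhat)
        return float(1.0 - 6.0 * np.sum(d**2) / (n * (n**2 - 1)))
    return pearson(_midranks(y), _midranks(yhat))


def roc_curve(labels, scores):
    """(FPR, TPR, thresholds) sweeping the decision threshold over scores.

    Tied scores are grouped so the curve steps once per distinct threshold.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels/scores length mismatch")
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    scores = scores[order]
    distinct = np.where(np.diff(scores))[0]
    idx = np.r_[distinct, labels.size - 1]
    tps = np.cumsum(labels)[idx]
    fps = (idx + 1) - tps
    P = labels.sum()
    N = labels.size - P
    tpr = np.r_[0.0, tps / max(P, 1)]
    fpr = np.r_[0.0, fps / max(N, 1)]
    thresholds = np.r_[np.inf, scores[idx]]
    return fpr, tpr, thresholds


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve by trapezoid; NaN if one class is absent."""
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        warnings.warn("roc_auc undefined for single-class labels; returning NaN")
        return float("nan")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def pr_curve(labels, scores):
    """(precision, recall, thresholds) for the positive class."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    scores = scores[order]
    distinct = np.where(np.diff(scores))[0]
    idx = np.r_[distinct, labels.size - 1]
    tps = np.cumsum(labels)[idx]
    fps = (idx + 1) - tps
    P = labels.sum()
    precision = tps / (tps + fps)
    recall = tps / max(P, 1)
    return np.r_[1.0, precision], np.r_[0.0, recall], np.r_[np.inf, scores[idx]]


def f1_at_threshold(labels, probs, threshold: float = 0.5) -> float:
    """F1 of the positive class at a fixed probability threshold."""
    labels = np.asarray(labels).ravel()
    pred = np.asarray(probs, dtype=float).ravel() > threshold
    tp = np.sum((pred == 1) & (labels == 1))
    fp = np.sum((pred == 1) & (labels == 0))
    fn = np.sum((pred == 0) & (labels == 1))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else float("nan")


def accuracy_at_threshold(labels, probs, threshold: float = 0.5) -> float:
    """Fraction of residues whose thresholded prediction matches the label."""
    labels = np.asarray(labels).ravel()
    pred = np.asarray(probs, dtype=float).ravel() > threshold
    return float(np.mean(pred == labels))


def evaluate_affinity(y, yhat) -> MetricsReport:
    y, yhat = _check_lengths(y, yhat)
    return MetricsReport(rmse=rmse(y, yhat), pearson=pearson(y, yhat),
                         spearman=spearman(y, yhat), n=int(y.size))


def evaluate_sites(labels, probs) -> MetricsReport:
    labels = np.asarray(labels).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    return MetricsReport(roc_auc=roc_auc(labels, probs),
                         f1=f1_at_threshold(labels, probs), n=int(labels.size))
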