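"""Pixel-overlap metrics for binary segmentation and the Focal Tversky loss.

All hard-mask metrics are pure functions of a :class:`ConfusionCounts`
(TP/FP/TN/FN pixel tallies), the shared currency between evaluation and
training.  The Tversky index TI = TP / (TP + a*FN + b*FP) generalises both
Dice (a = b = 0.5) and Jaccard (a = b = 1); the focal loss is (1 - TI)^gamma
computed on soft (probabilistic) counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "TverskyParams", "confusion_counts", "accuracy",
    "dice", "jaccard", "threshold_jaccard", "tversky", "focal_tversky_loss",
    "soft_tversky_index",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel agreement tallies between a predicted and a true mask."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class TverskyParams:
    """Weights for the (focal) Tversky loss.

    alpha weights false negatives, beta false positives; gamma is the focal
    exponent; epsilon smooths the soft ratio away from 0/0.  alpha > beta
    (default 0.7/0.3) penalises missed lesion pixels harder, which suits the
    strong background/lesion class imbalance of dermoscopy.
    """

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 4.0 / 3.0
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(np.int64)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN pixels between two binary masks of identical shape."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}")
    p = _check_binary(pred, "prediction")
    g = _check_binary(gt, "ground truth")
    tp = int((p & g).sum())
    fp = int((p & (1 - g)).sum())
    fn = int(((1 - p) & g).sum())
    tn = int(((1 - p) & (1 - g)).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of pixels labelled correctly."""
    if c.total == 0:
        raise ValueError("accuracy is undefined for empty masks (zero pixels)")
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Dice similarity 2TP/(2TP+FP+FN); both-empty masks score `empty_value`."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return 2 * c.tp / denom


def jaccard(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """Jaccard index TP/(TP+FP+FN); both-empty masks score `empty_value`."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return c.tp / denom


def threshold_jaccard(jsi: float, threshold: float = 0.65) -> float:
    """Zero below the usability cutoff, identity at and above it."""
    if not 0.0 <= jsi <= 1.0:
        raise ValueError(f"JSI must lie in [0, 1], got {jsi}")
    return 0.0 if jsi < threshold else jsi


def tversky(c: ConfusionCounts, alpha: float, beta: float,
            empty_value: float = 1.0) -> float:
    """Tversky index TP/(TP + alpha*FN + beta*FP)."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    denom = c.tp + alpha * c.fn + beta * c.fp
    if denom == 0:
        return empty_value
    return c.tp / denom


def soft_tversky_index(pred_probs: np.ndarray, gt: np.ndarray,
                       params: TverskyParams) -> np.ndarray:
    """Soft TI per image from foreground probabilities (ndarray path)."""
    p = np.asarray(pred_probs, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs mask {g.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    if p.ndim == 2:
        p, g = p[None], g[None]
    axes = tuple(range(1, p.ndim))
    tp = (p * g).sum(axis=axes)
    fn = ((1.0 - p) * g).sum(axis=axes)
    fp = (p * (1.0 - g)).sum(axis=axes)
    eps = params.epsilon
    return (tp + eps) / (tp + params.alpha * fn + params.beta * fp + eps)


def focal_tversky_loss(pred_probs: np.ndarray, gt: np.ndarray,
                       params: TverskyParams | None = None) -> float:
    """Focal Tversky loss (1 - TI)^gamma averaged per image.

    Accepts one image (H, W) or a batch (N, H, W) of foreground-probability
    maps plus binary ground truth of the same shape.
    """
    params = params or TverskyParams()
    _check_binary(gt, "ground truth")
    ti = soft_tversky_index(pred_probs, gt, params)
    return float(np.mean((1.0 - ti) ** params.gamma))
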