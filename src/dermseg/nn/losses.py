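"""Differentiable segmentation losses on autodiff tensors."""

from __future__ import annotations

import numpy as np

from ..metrics import TverskyParams
from .tensor import Tensor, div, slice_channels, tmean, tsum


def soft_tversky_index(probs: Tensor, target: np.ndarray,
                       params: TverskyParams) -> Tensor:
    """Per-image soft Tversky index from 2-class softmax output.

    probs: (N, 2, H, W) with channel 1 = lesion foreground.
    target: (N, H, W) binary ground truth.
    Soft counts use the foreground probability p: TP = sum(p*g),
    FN = sum((1-p)*g), FP = sum(p*(1-g)); both numerator and denominator
    carry the smoothing epsilon.  Returns a length-N tensor.
    """
    target = np.asarray(target, dtype=np.float32)
    if target.ndim == 2:
        target = target[None]
    p = slice_channels(probs, 1, 2)  # (N,1,H,W)
    g = target[:, None]
    tp = tsum(p * g, axis=(1, 2, 3))
    fn = tsum((1.0 - p) * g, axis=(1, 2, 3))
    fp = tsum(p * (1.0 - g), axis=(1, 2, 3))
    eps = params.epsilon
    return div(tp + eps, tp + params.alpha * fn + params.beta * fp + eps)


def focal_tversky(probs: Tensor, target: np.ndarray,
                  params: TverskyParams | None = None) -> Tensor:
    """Focal Tversky loss (1 - TI)^gamma, averaged per image over the batch."""
    params = params or TverskyParams()
    ti = soft_tversky_index(probs, target, params)
    return tmean((1.0 - ti) ** params.gamma)
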