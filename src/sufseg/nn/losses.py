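"""Differentiable loss graph counterparts of :mod:`sufseg.metrics`.

These build autodiff graphs for training; the NumPy implementations in
``sufseg.metrics`` are the reference the tests cross-check against.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, bce_logits, clip_values, sigmoid, square, tlog, tmean, tsum

__all__ = [
    "dice_loss_t",
    "bce_loss_t",
    "mse_loss_t",
    "compound_loss_t",
    "tversky_loss_t",
    "compound_loss_logits_t",
    "tversky_loss_logits_t",
]

_EPS = 1e-6


def _pair(pred: Tensor, target) -> tuple[Tensor, Tensor]:
    tgt = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=pred.data.dtype))
    if pred.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {tgt.shape}")
    return pred, tgt


def _soft_axes(pred: Tensor):
    """Per-(sample, channel) reduction for 5-D tensors, global otherwise."""
    return tuple(range(2, len(pred.shape))) if len(pred.shape) == 5 else None


def dice_loss_t(pred: Tensor, target, eps: float = _EPS) -> Tensor:
    pred, tgt = _pair(pred, target)
    ax = _soft_axes(pred)
    inter = tsum(pred * tgt, axis=ax)
    denom = tsum(pred, axis=ax) + tsum(tgt, axis=ax)
    two = Tensor(np.asarray(2.0, dtype=pred.data.dtype))
    e = Tensor(np.asarray(eps, dtype=pred.data.dtype))
    dice = (two * inter + e) / (denom + e)
    return Tensor(np.asarray(1.0, dtype=pred.data.dtype)) - tmean(dice)


def bce_loss_t(pred: Tensor, target, eps: float = 1e-7) -> Tensor:
    pred, tgt = _pair(pred, target)
    p = clip_values(pred, eps, 1.0 - eps)
    one = Tensor(np.asarray(1.0, dtype=pred.data.dtype))
    return -tmean(tgt * tlog(p) + (one - tgt) * tlog(one - p))


def mse_loss_t(pred: Tensor, target) -> Tensor:
    pred, tgt = _pair(pred, target)
    return tmean(square(pred - tgt))


def compound_loss_t(pred: Tensor, target) -> Tensor:
    """Dice + BCE + MSE, the training objective for the x0-hat prediction."""
    return dice_loss_t(pred, target) + bce_loss_t(pred, target) + mse_loss_t(pred, target)


def compound_loss_logits_t(logits: Tensor, target) -> Tensor:
    """Training form of the compound loss, fed with pre-sigmoid logits.

    Dice and MSE act on sigmoid(logits); BCE is evaluated in logit space so
    its gradient (s - t) survives float32 saturation of the probabilities.
    Numerically equal to ``compound_loss_t(sigmoid(logits), target)`` up to
    the BCE clipping epsilon.
    """
    p = sigmoid(logits)
    return dice_loss_t(p, target) + bce_logits(logits, target) + mse_loss_t(p, target)


def tversky_loss_logits_t(logits: Tensor, target, alpha: float = 0.7, beta: float = 0.3) -> Tensor:
    """Tversky evaluated on sigmoid(logits)."""
    return tversky_loss_t(sigmoid(logits), target, alpha, beta)


def tversky_loss_t(pred: Tensor, target, alpha: float = 0.7, beta: float = 0.3, eps: float = _EPS) -> Tensor:
    if alpha < 0 or beta < 0 or alpha + beta == 0:
        raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
    pred, tgt = _pair(pred, target)
    dt = pred.data.dtype
    one = Tensor(np.asarray(1.0, dtype=dt))
    ax = _soft_axes(pred)
    tp = tsum(pred * tgt, axis=ax)
    fp = tsum(pred * (one - tgt), axis=ax)
    fn = tsum((one - pred) * tgt, axis=ax)
    e = Tensor(np.asarray(eps, dtype=dt))
    a = Tensor(np.asarray(alpha, dtype=dt))
    b = Tensor(np.asarray(beta, dtype=dt))
    return one - tmean((tp + e) / (tp + a * fp + b * fn + e))
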