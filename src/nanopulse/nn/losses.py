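"""Smooth-L1 (Huber, beta = 1) loss with its gradient."""

from __future__ import annotations

import numpy as np

__all__ = ["smooth_l1", "smooth_l1_grad", "smooth_l1_mean"]


def smooth_l1(x, y):
    """Elementwise smooth-L1: 0.5 (x-y)^2 where |x-y| < 1, |x-y| - 0.5 outside.

    Continuous with continuous first derivative at |x-y| = 1; gradient
    magnitude never exceeds 1.
    """
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    out = np.where(d < 1.0, 0.5 * d * d, d - 0.5)
    return float(out) if out.ndim == 0 else out


def smooth_l1_grad(x, y):
    """d/dx of the elementwise loss: clip(x - y, -1, 1)."""
    return np.clip(np.asarray(x, dtype=float) - np.asarray(y, dtype=float),
                   -1.0, 1.0)


def smooth_l1_mean(pred: np.ndarray, target: np.ndarray):
    """Mean loss over all elements and its gradient w.r.t. ``pred``."""
    loss = float(np.mean(smooth_l1(pred, target)))
    grad = (smooth_l1_grad(pred, target) / pred.size).astype(pred.dtype)
    return loss, grad
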