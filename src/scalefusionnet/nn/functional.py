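"""Stateless differentiable operations: resizing, deformable sampling, losses."""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .tensor import Tensor

__all__ = [
    "bilinear_resize",
    "bilinear_sample",
    "bce_loss",
    "soft_iou",
]


def _resize_taps(n_in: int, n_out: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-pixel-centred source taps and weights for 1-D linear resize."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    i0 = np.floor(src).astype(np.int64)
    t = (src - i0).astype(np.float32)
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, t


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of a (B, C, H, W) tensor (half-pixel convention)."""
    B, C, H, W = x.shape
    if (H, W) == (out_h, out_w):
        return x
    y0, y1, ty = _resize_taps(H, out_h)
    x0, x1, tx = _resize_taps(W, out_w)
    ty = ty.reshape(1, 1, out_h, 1)
    tx = tx.reshape(1, 1, 1, out_w)

    def gather(yi, xi):
        return x[:, :, yi[:, None], xi[None, :]]

    top = gather(y0, x0) * (1 - tx) + gather(y0, x1) * tx
    bot = gather(y1, x0) * (1 - tx) + gather(y1, x1) * tx
    return top * (1 - ty) + bot * ty


def bilinear_sample(x: Tensor, pos_y: Tensor, pos_x: Tensor) -> Tensor:
    """Sample (B, C, H, W) at fractional positions with zero padding outside.

    ``pos_y``/``pos_x`` have shape (B, K, Ho, Wo); the result is
    (B, C, K, Ho, Wo).  Gradients flow to both the map and the positions
    (through the interpolation weights; the integer lattice is detached).
    """
    B, C, H, W = x.shape
    _, K, Ho, Wo = pos_y.shape
    y0 = np.floor(pos_y.data).astype(np.int64)
    x0 = np.floor(pos_x.data).astype(np.int64)
    ty = pos_y - Tensor(y0.astype(np.float32))
    tx = pos_x - Tensor(x0.astype(np.float32))
    bI = np.arange(B).reshape(B, 1, 1, 1, 1)
    cI = np.arange(C).reshape(1, C, 1, 1, 1)

    def tap(yi, xi):
        valid = ((yi >= 0) & (yi < H) & (xi >= 0) & (xi < W))
        yc = np.clip(yi, 0, H - 1)[:, None]
        xc = np.clip(xi, 0, W - 1)[:, None]
        v = x[bI, cI, yc, xc]  # (B, C, K, Ho, Wo)
        return v * Tensor(valid[:, None].astype(np.float32))

    one = 1.0
    wy0, wy1 = (one - ty), ty
    wx0, wx1 = (one - tx), tx
    # broadcast weights over the channel axis
    def w(t):
        return t.reshape(B, 1, K, Ho, Wo)

    out = (
        tap(y0, x0) * (w(wy0) * w(wx0))
        + tap(y0, x0 + 1) * (w(wy0) * w(wx1))
        + tap(y0 + 1, x0) * (w(wy1) * w(wx0))
        + tap(y0 + 1, x0 + 1) * (w(wy1) * w(wx1))
    )
    return out


def bce_loss(p: Tensor, target: Tensor, eps: float = 1e-6) -> Tensor:
    """Mean binary cross-entropy on probabilities.

    Probabilities are squeezed affinely into [eps, 1-eps] rather than
    clipped, so the gradient never dies when the network saturates.
    """
    pc = p * (1.0 - 2.0 * eps) + eps
    ll = target * pc.log() + (1.0 - target) * (1.0 - pc).log()
    return -ll.mean()


def soft_iou(p: Tensor, target: Tensor, eps: float = 1e-6) -> Tensor:
    """Differentiable intersection-over-union on probabilities."""
    inter = (p * target).sum()
    union = p.sum() + target.sum() - inter
    return (inter + eps) / (union + eps)
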