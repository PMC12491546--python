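"""Window-attention primitives shared by the encoder, CATM and AFB.

Feature maps are ``Tensor`` objects laid out (batch, channels, height, width).
Attention operates on windows of ``window_size**2`` tokens; the default window
is 8 so that all four pyramid resolutions of a 256x256 input (64, 32, 16, 8)
partition evenly.  Maps no larger than the window collapse to a single global
window and the shifted variant is skipped there, since a cyclic shift would
wrap the entire map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "WindowConfig",
    "PatchEmbed",
    "WindowAttention",
    "SwinBlock",
    "PatchMerging",
    "window_partition",
    "window_reverse",
]


@dataclass(frozen=True)
class WindowConfig:
    """Hyperparameters of one windowed-attention block."""

    window_size: int = 8
    num_heads: int = 3
    embed_dim: int = 96
    shift: int = 0

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.embed_dim % self.num_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"num_heads {self.num_heads}"
            )
        if self.shift not in (0, self.window_size // 2):
            raise ValueError("shift must be 0 or window_size/2")


def window_partition(x: Tensor, window_size: int) -> Tuple[Tensor, tuple]:
    """Split a (B, C, H, W) map into (B*nw, window_size**2, C) token windows.

    Non-divisible maps are zero-padded symmetrically first; the returned
    ``meta`` carries what :func:`window_reverse` needs to undo both the
    partition and the padding.  Window order is row-major with batch slowest.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    B, C, H, W = x.shape
    w = window_size
    ph, pw = (-H) % w, (-W) % w
    t = x.transpose(0, 2, 3, 1)  # (B, H, W, C)
    if ph or pw:
        t = t.pad2d(ph // 2, ph - ph // 2, pw // 2, pw - pw // 2, axes=(1, 2))
    Hp, Wp = H + ph, W + pw
    t = t.reshape(B, Hp // w, w, Wp // w, w, C)
    t = t.transpose(0, 1, 3, 2, 4, 5)  # (B, nH, nW, w, w, C)
    windows = t.reshape(B * (Hp // w) * (Wp // w), w * w, C)
    meta = (B, C, H, W, Hp, Wp, w)
    return windows, meta


def window_reverse(windows: Tensor, meta: tuple) -> Tensor:
    """Inverse of :func:`window_partition` (crops any padding)."""
    B, C, H, W, Hp, Wp, w = meta
    t = windows.reshape(B, Hp // w, Wp // w, w, w, C)
    t = t.transpose(0, 1, 3, 2, 4, 5).reshape(B, Hp, Wp, C)
    ph, pw = Hp - H, Wp - W
    if ph or pw:
        t = t[:, ph // 2 : ph // 2 + H, pw // 2 : pw // 2 + W, :]
    return t.transpose(0, 3, 1, 2)


def _relative_position_index(side: int, table_window: int) -> np.ndarray:
    """Index into the (2*table_window-1)^2 bias table for a side x side
    window (side <= table_window; smaller sides arise when a map collapses
    to global attention)."""
    coords = np.stack(
        np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    )
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, T, T)
    rel = rel.transpose(1, 2, 0) + (table_window - 1)
    return rel[:, :, 0] * (2 * table_window - 1) + rel[:, :, 1]  # (T, T)


class WindowAttention(nn.Module):
    """Multi-head self-attention within a window, with relative position bias."""

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 rng: Optional[np.random.Generator] = None):
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        rng = rng or np.random.default_rng()
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = window_size
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.rel_bias = nn.Parameter(
            nn.trunc_normal(rng, ((2 * window_size - 1) ** 2, num_heads))
        )
        self._rel_index_cache: dict = {}

    def _bias(self, T: int) -> Tensor:
        side = int(round(T ** 0.5))
        if side * side == T and side <= self.window_size:
            key = ("sq", side)
            if key not in self._rel_index_cache:
                self._rel_index_cache[key] = _relative_position_index(
                    side, self.window_size
                ).reshape(-1)
        else:
            # non-square token sets (partial windows): leading positions of
            # the full window, row-major
            key = ("lead", T)
            if key not in self._rel_index_cache:
                full = _relative_position_index(
                    self.window_size, self.window_size
                )
                self._rel_index_cache[key] = full[:T, :T].reshape(-1)
        idx = self._rel_index_cache[key]
        b = self.rel_bias[idx]  # (T*T, heads)
        return b.reshape(T, T, self.num_heads).transpose(2, 0, 1)

    def forward(self, tokens: Tensor, mask: Optional[np.ndarray] = None,
                return_attn: bool = False):
        """``tokens``: (B_, T, C). ``mask``: additive (nw, T, T) or None."""
        B_, T, C = tokens.shape
        if C != self.dim:
            raise ValueError(f"token dim {C} != configured {self.dim}")
        h, dh = self.num_heads, self.dim // self.num_heads
        qkv = self.qkv(tokens).reshape(B_, T, 3, h, dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B_, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        bias = self._bias(T).reshape(1, h, T, T)
        scores = scores + bias
        if mask is not None:
            nw = mask.shape[0]
            scores = scores.reshape(B_ // nw, nw, h, T, T) + Tensor(
                mask[None, :, None]
            )
            scores = scores.reshape(B_, h, T, T)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B_, T, C)
        out = self.proj(out)
        if return_attn:
            return out, attn
        return out


def _shift_mask(Hp: int, Wp: int, w: int, shift: int) -> np.ndarray:
    """Additive attention mask preventing cross-segment mixing after a roll."""
    img = np.zeros((Hp, Wp), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, -w), slice(-w, -shift), slice(-shift, None)):
        for ws in (slice(0, -w), slice(-w, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    win = img.reshape(Hp // w, w, Wp // w, w).transpose(0, 2, 1, 3)
    win = win.reshape(-1, w * w)
    diff = win[:, None, :] != win[:, :, None]
    return np.where(diff, -100.0, 0.0).astype(np.float32)


class SwinBlock(nn.Module):
    """Pre-norm transformer block: x + W-MSA(LN(x)), then + MLP(LN(.)).

    MLP expansion ratio is 4 with GELU.  ``shift`` > 0 gives the shifted-
    window variant; shifting is skipped when the map is not larger than the
    window (the block then degenerates to global attention).
    """

    def __init__(self, cfg: WindowConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        d = cfg.embed_dim
        self.norm1 = nn.LayerNorm(d)
        self.attn = WindowAttention(d, cfg.num_heads, cfg.window_size, rng=rng)
        self.norm2 = nn.LayerNorm(d)
        self.mlp_fc1 = nn.Linear(d, 4 * d, rng=rng)
        self.mlp_fc2 = nn.Linear(4 * d, d, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        # maps smaller than the window collapse to global attention
        w = min(self.cfg.window_size, H, W)
        shift = self.cfg.shift and (w // 2)
        if min(H, W) <= w or H % w or W % w:
            shift = 0  # global/padded attention; a roll would wrap the map
        t = x.transpose(0, 2, 3, 1).reshape(B, H * W, C)
        t = self.norm1(t).reshape(B, H, W, C).transpose(0, 3, 1, 2)
        if shift:
            t = t.roll((-shift, -shift), axes=(2, 3))
        windows, meta = window_partition(t, w)
        mask = None
        if shift:
            mask = _shift_mask(meta[4], meta[5], w, shift)
        windows = self.attn(windows, mask=mask)
        t = window_reverse(windows, meta)
        if shift:
            t = t.roll((shift, shift), axes=(2, 3))
        x = x + t
        t = x.transpose(0, 2, 3, 1).reshape(B, H * W, C)
        t = self.mlp_fc2(self.mlp_fc1(self.norm2(t)).gelu())
        t = t.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        return x + t


def swin_stack(dim: int, depth: int, num_heads: int, window_size: int,
               rng: np.random.Generator) -> nn.ModuleList:
    """``depth`` blocks alternating shift 0 / window_size//2."""
    blocks = []
    for i in range(depth):
        shift = 0 if i % 2 == 0 else window_size // 2
        blocks.append(
            SwinBlock(WindowConfig(window_size, num_heads, dim, shift), rng=rng)
        )
    return nn.ModuleList(blocks)


class PatchEmbed(nn.Module):
    """4x4 stride-4 convolution + layer normalization (the conv stem)."""

    def __init__(self, embed_dim: int, in_ch: int = 3,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.proj = nn.Conv2d(in_ch, embed_dim, 4, stride=4, rng=rng)
        self.norm = nn.LayerNorm(embed_dim)
        self.embed_dim = embed_dim

    def forward(self, image: Tensor) -> Tensor:
        B, C, H, W = image.shape
        if H % 4 or W % 4:
            raise ValueError(f"spatial dims ({H},{W}) must be divisible by 4")
        x = self.proj(image)
        B, D, Ho, Wo = x.shape
        t = x.transpose(0, 2, 3, 1).reshape(B, Ho * Wo, D)
        t = self.norm(t)
        return t.reshape(B, Ho, Wo, D).transpose(0, 3, 1, 2)


class PatchMerging(nn.Module):
    """2x2 neighborhood concatenation + linear reduction (H,W halve, C doubles)."""

    def __init__(self, dim: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.dim = dim
        self.norm = nn.LayerNorm(4 * dim)
        self.reduction = nn.Linear(4 * dim, 2 * dim, rng=rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"patch merging needs even dims, got ({H},{W})")
        t = x.transpose(0, 2, 3, 1)  # (B, H, W, C)
        x0 = t[:, 0::2, 0::2, :]
        x1 = t[:, 1::2, 0::2, :]
        x2 = t[:, 0::2, 1::2, :]
        x3 = t[:, 1::2, 1::2, :]
        cat = nn.concat([x0, x1, x2, x3], axis=-1)  # (B, H/2, W/2, 4C)
        cat = cat.reshape(B, (H // 2) * (W // 2), 4 * C)
        out = self.reduction(self.norm(cat))
        return out.reshape(B, H // 2, W // 2, 2 * C).transpose(0, 3, 1, 2)
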