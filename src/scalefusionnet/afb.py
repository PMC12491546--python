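"""Adaptive Fusion Block (AFB): three parallel branches fused by 1x1 reduction.

For a decoder feature ``X`` the block computes::

    X_Swin    = resolution-aware windowed-attention branch (see below)
    Offset    = Conv3x3(X)                     # zero-initialized
    X_Deform  = DeformConv3x3(X, Offset)       # bilinear sampling
    X_Out     = Conv1x1(concat(X, X_Swin, X_Deform))

The attention branch adapts to the level's spatial resolution: level 0
(64x64) runs the first two stages' worth of blocks, level 1 (32x32) three
stages, level 2 (16x16) all four with a halved internal embedding, and at
level 3 (8x8) attention is dropped entirely in favour of a plain 3x3
convolution.  Blocks run at constant resolution (no patch merging): the
three-way concatenation requires matched H x W.  Entry/exit 1x1 projections
map the level's channel count onto the branch's internal width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor, bilinear_sample
from .swin_core import swin_stack

__all__ = [
    "SWIN_TINY_DEPTHS",
    "AfbLevelPolicy",
    "SwinBranch",
    "DeformConv2d",
    "DeformBranch",
    "Afb",
]

SWIN_TINY_DEPTHS = (2, 2, 6, 2)

# level -> (number of attention stages, halve internal embedding)
_LEVEL_TABLE = {0: (2, False), 1: (3, False), 2: (4, True), 3: (0, False)}


@dataclass(frozen=True)
class AfbLevelPolicy:
    """Resolution policy of the attention branch at one decoder level."""

    level: int
    swin_stages_used: int
    reduce_embed: bool

    @classmethod
    def for_level(cls, level: int) -> "AfbLevelPolicy":
        if level not in _LEVEL_TABLE:
            raise ValueError(f"level must be 0..3, got {level}")
        stages, reduce = _LEVEL_TABLE[level]
        return cls(level=level, swin_stages_used=stages, reduce_embed=reduce)

    @property
    def depth(self) -> int:
        return sum(SWIN_TINY_DEPTHS[: self.swin_stages_used])


def _heads_for(width: int) -> int:
    for h in (6, 4, 3, 2, 1):
        if width % h == 0:
            return h
    return 1


class SwinBranch(nn.Module):
    """Constant-resolution attention branch, or a plain conv at level 3."""

    def __init__(self, dim: int, policy: AfbLevelPolicy, base_width: int,
                 window_size: int = 8,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.dim = dim
        self.policy = policy
        if policy.depth == 0:
            self.internal_width = 0
            self.conv = nn.Conv2d(dim, dim, 3, padding=1, rng=rng)
        else:
            w = base_width // 2 if policy.reduce_embed else base_width
            self.internal_width = w
            self.entry = nn.Conv2d(dim, w, 1, rng=rng)
            self.blocks = swin_stack(
                w, policy.depth, _heads_for(w), window_size, rng
            )
            self.exit = nn.Conv2d(w, dim, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {x.shape[1]}")
        if self.policy.depth == 0:
            return self.conv(x)
        t = self.entry(x)
        for block in self.blocks:
            t = block(t)
        return self.exit(t)


class DeformConv2d(nn.Module):
    """3x3 deformable convolution; one deformable group, bilinear sampling,
    zero padding outside the map.

    ``offset`` is (B, 18, H, W): channels 0..8 are per-tap row displacements,
    channels 9..17 the column displacements, taps in row-major kernel order.
    """

    def __init__(self, in_ch: int, out_ch: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * 9
        self.weight = nn.Parameter(
            (rng.standard_normal((out_ch, in_ch, 3, 3))
             * np.sqrt(2.0 / fan_in)).astype(np.float32)
        )
        self.bias = nn.Parameter(np.zeros(out_ch, dtype=np.float32))
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x: Tensor, offset: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if offset.shape != (B, 18, H, W):
            raise ValueError(
                f"offset shape {offset.shape} != {(B, 18, H, W)}"
            )
        taps = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)],
                        dtype=np.float32)
        gy, gx = np.meshgrid(np.arange(H, dtype=np.float32),
                             np.arange(W, dtype=np.float32), indexing="ij")
        base_y = gy[None] + taps[:, 0][:, None, None]   # (9, H, W)
        base_x = gx[None] + taps[:, 1][:, None, None]
        pos_y = offset[:, 0:9] + Tensor(base_y[None])
        pos_x = offset[:, 9:18] + Tensor(base_x[None])
        val = bilinear_sample(x, pos_y, pos_x)          # (B, C, 9, H, W)
        wm = self.weight.reshape(self.out_ch, C * 9)
        out = wm @ val.reshape(B, C * 9, H * W)
        out = out + self.bias.reshape(1, self.out_ch, 1)
        return out.reshape(B, self.out_ch, H, W)


class DeformBranch(nn.Module):
    """Offset predictor (zero-initialized 3x3 conv) + deformable convolution.

    Zero initialization means the first forward pass samples the regular
    grid, i.e. the branch starts as a standard 3x3 convolution.
    """

    def __init__(self, dim: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.offset_conv = nn.Conv2d(dim, 18, 3, padding=1, rng=rng,
                                     zero_init=True)
        self.deform = DeformConv2d(dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.deform(x, self.offset_conv(x))


class Afb(nn.Module):
    """Full block: attention + deformable + identity branches, concat, 1x1."""

    def __init__(self, dim: int, level: int, base_width: int,
                 window_size: int = 8,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.dim = dim
        self.policy = AfbLevelPolicy.for_level(level)
        self.swin_branch = SwinBranch(dim, self.policy, base_width,
                                      window_size, rng=rng)
        self.deform_branch = DeformBranch(dim, rng=rng)
        self.reduce = nn.Conv2d(3 * dim, dim, 1, rng=rng)

    def fuse(self, x: Tensor, x_swin: Tensor, x_deform: Tensor) -> Tensor:
        if not (x.shape == x_swin.shape == x_deform.shape):
            raise ValueError(
                f"branch shapes differ: {x.shape}, {x_swin.shape}, "
                f"{x_deform.shape}"
            )
        return self.reduce(nn.concat([x, x_swin, x_deform], axis=1))

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(x, self.swin_branch(x), self.deform_branch(x))
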