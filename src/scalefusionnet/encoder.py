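"""Hierarchical four-stage encoder producing the skip-connection pyramid.

For a 256x256 RGB input the four stage outputs (taken *before* each patch
merging, so channel counts match the skip arrows) are::

    level 0: (96,  64, 64)
    level 1: (192, 32, 32)
    level 2: (384, 16, 16)
    level 3: (768,  8,  8)
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from . import nn
from .nn import Tensor
from .swin_core import PatchEmbed, PatchMerging, swin_stack

__all__ = ["SwinEncoder"]


class SwinEncoder(nn.Module):
    """Conv patch-embedding stem followed by four windowed-attention stages.

    Defaults follow the Tiny configuration: depths (2, 2, 6, 2), heads
    (3, 6, 12, 24), base embedding 96.
    """

    def __init__(self, embed_dim: int = 96,
                 depths=(2, 2, 6, 2), num_heads=(3, 6, 12, 24),
                 window_size: int = 8,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.embed_dim = embed_dim
        self.patch_embed = PatchEmbed(embed_dim, rng=rng)
        self.stages = nn.ModuleList()
        self.merges = nn.ModuleList()
        dim = embed_dim
        for i, (depth, heads) in enumerate(zip(depths, num_heads)):
            self.stages.append(swin_stack(dim, depth, heads, window_size, rng))
            if i < len(depths) - 1:
                self.merges.append(PatchMerging(dim, rng=rng))
                dim *= 2
        self.channels = [embed_dim * (2 ** i) for i in range(len(depths))]

    def forward(self, image: Tensor) -> List[Tensor]:
        """Return the four pre-merging stage outputs (the skip sources)."""
        if image.shape[1] != 3:
            raise ValueError(f"expected 3 input channels, got {image.shape[1]}")
        x = self.patch_embed(image)
        skips: List[Tensor] = []
        for i, stage in enumerate(self.stages):
            for block in stage:
                x = block(x)
            skips.append(x)
            if i < len(self.merges):
                x = self.merges[i](x)
        return skips
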