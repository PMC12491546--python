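"""Cross-Attention Transformer Module (CATM).

At each skip connection the decoder feature drives a windowed cross-attention
over projected Q/K/V tokens:

    Q, K, V = proj(SwinBlock(source))
    V'      = softmax(Q K^T / sqrt(d_k)) V          (window-local)
    X'_Skip = CAF(V', X_Skip)                        (concat + 1x1 + LN + GELU)
    A       = sigmoid(SharedConv1x1([proj(X'), avg_c(X'), max_c(X')]))
    X_CATM  = X'_Skip * A

The Q/K/V routing is configurable; by default all three derive from the
decoder feature.  The pooling inside the spatial attention runs across the
channel axis so that ``A`` keeps the full H x W extent, and the final 3->1
convolution + sigmoid is a single parameter set shared by every level
("SharedSA"); a small per-level C->1 projection absorbs the differing channel
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .swin_core import SwinBlock, WindowConfig, window_partition, window_reverse

__all__ = [
    "ROUTINGS",
    "CatmConfig",
    "SharedSpatialAttention",
    "Catm",
    "cross_attention",
]

#: Q/K/V source table; each entry maps routing -> (q_source, k_source, v_source)
ROUTINGS = {
    "decoder_all": ("dec", "dec", "dec"),
    "q_dec_kv_skip": ("dec", "skip", "skip"),
    "q_skip_kv_dec": ("skip", "dec", "dec"),
    "qk_dec_v_skip": ("dec", "dec", "skip"),
}


@dataclass(frozen=True)
class CatmConfig:
    qkv_routing: str = "decoder_all"
    use_shared_sa: bool = True
    window_size: int = 8

    def __post_init__(self):
        if self.qkv_routing not in ROUTINGS:
            raise ValueError(
                f"unknown routing {self.qkv_routing!r}; "
                f"valid: {sorted(ROUTINGS)}"
            )


def cross_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Single-head scaled dot-product attention on token stacks (B_, T, C).

    ``d_k`` is the channel dimension of K.
    """
    if q.shape[1] != k.shape[1] or k.shape != v.shape:
        raise ValueError(
            f"token mismatch: q {q.shape}, k {k.shape}, v {v.shape}"
        )
    d_k = k.shape[-1]
    scores = (q @ k.transpose(0, 2, 1)) * (d_k ** -0.5)
    return scores.softmax(axis=-1) @ v


class SharedSpatialAttention(nn.Module):
    """The level-shared 3->1 convolution + sigmoid of the spatial attention.

    One instance is created per network and reused at every CATM level; its
    parameter count is therefore independent of how many levels exist.
    """

    def __init__(self, rng: Optional[np.random.Generator] = None):
        self.conv = nn.Conv2d(3, 1, 1, rng=rng)

    def forward(self, descriptors: Tensor) -> Tensor:
        return self.conv(descriptors).sigmoid()


class Catm(nn.Module):
    """One CATM instance, bound to a skip level of channel width ``dim``."""

    def __init__(self, dim: int, num_heads: int, shared_sa: SharedSpatialAttention,
                 cfg: CatmConfig = CatmConfig(),
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.dim = dim
        self.cfg = cfg
        self.block = SwinBlock(
            WindowConfig(cfg.window_size, num_heads, dim, shift=0), rng=rng
        )
        self.proj_q = nn.Linear(dim, dim, rng=rng)
        self.proj_k = nn.Linear(dim, dim, rng=rng)
        self.proj_v = nn.Linear(dim, dim, rng=rng)
        self.caf_reduce = nn.Conv2d(2 * dim, dim, 1, rng=rng)
        self.caf_norm = nn.LayerNorm(dim)
        if cfg.use_shared_sa:
            if shared_sa is None:
                raise ValueError("use_shared_sa requires a SharedSpatialAttention")
            self.sa_proj = nn.Conv2d(dim, 1, 1, rng=rng)  # per-level, not shared
            self.shared_sa = shared_sa
        else:  # ablation without SharedSA: its parameters are not built
            self.sa_proj = None
            self.shared_sa = None

    # ------------------------------------------------------------------ steps
    def derive_qkv(self, x_decoder: Tensor,
                   x_skip: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        """Project Q, K, V from the routed sources after one Swin block."""
        if x_decoder.shape[2:] != x_skip.shape[2:]:
            raise ValueError(
                f"skip {x_skip.shape} and decoder {x_decoder.shape} "
                "spatial dims differ; upsample the decoder feature first"
            )
        srcs = ROUTINGS[self.cfg.qkv_routing]
        feats = {}
        for name, x in (("dec", x_decoder), ("skip", x_skip)):
            if name in srcs:
                f = self.block(x)
                B, C, H, W = f.shape
                feats[name] = f.transpose(0, 2, 3, 1).reshape(B, H * W, C)
        q = self.proj_q(feats[srcs[0]])
        k = self.proj_k(feats[srcs[1]])
        v = self.proj_v(feats[srcs[2]])
        return q, k, v

    def caf(self, v_prime: Tensor, x_skip: Tensor) -> Tensor:
        """Cross-attention fusion: concat + 1x1 reduction + LN + GELU."""
        if v_prime.shape != x_skip.shape:
            raise ValueError(
                f"shape mismatch in CAF: {v_prime.shape} vs {x_skip.shape}"
            )
        fused = self.caf_reduce(nn.concat([v_prime, x_skip], axis=1))
        B, C, H, W = fused.shape
        t = fused.transpose(0, 2, 3, 1).reshape(B, H * W, C)
        t = self.caf_norm(t).gelu()
        return t.reshape(B, H, W, C).transpose(0, 3, 1, 2)

    def shared_spatial_attention(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        """Return (attention map A in (0,1), X * A)."""
        if self.shared_sa is None:
            raise RuntimeError("spatial attention disabled in this config")
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        desc = nn.concat([self.sa_proj(x), avg, mx], axis=1)
        a = self.shared_sa(desc)
        return a, x * a

    # ---------------------------------------------------------------- forward
    def refine(self, x_skip: Tensor, x_decoder: Tensor) -> Tensor:
        """X'_Skip: windowed cross-attention + CAF, before spatial attention."""
        q, k, v = self.derive_qkv(x_decoder, x_skip)
        B, C, H, W = x_skip.shape
        maps = [t.reshape(B, H, W, C).transpose(0, 3, 1, 2) for t in (q, k, v)]
        wins = []
        meta = None
        w_eff = min(self.cfg.window_size, H, W)
        for m in maps:
            wtok, meta = window_partition(m, w_eff)
            wins.append(wtok)
        v_prime = cross_attention(*wins)
        v_prime = window_reverse(v_prime, meta)
        return self.caf(v_prime, x_skip)

    def forward(self, x_skip: Tensor, x_decoder: Tensor) -> Tensor:
        x_ref = self.refine(x_skip, x_decoder)
        if not self.cfg.use_shared_sa:
            return x_ref
        _, x_catm = self.shared_spatial_attention(x_ref)
        return x_catm
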