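"""Optimizers. AdamW with decoupled weight decay is the only one the
training recipe needs (lr = wd = 1e-4 in the reference configuration)."""

from __future__ import annotations

from typing import List

import numpy as np

from .modules import Parameter

__all__ = ["AdamW", "clip_grad_norm"]


def clip_grad_norm(params: List["Parameter"], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = total ** 0.5
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
    return norm


class AdamW:
    def __init__(self, params: List[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )
            p.data = p.data.astype(np.float32)
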