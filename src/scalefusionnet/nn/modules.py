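"""Layer abstractions over the autograd :class:`~scalefusionnet.nn.tensor.Tensor`.

Initialization follows the Swin convention: truncated-normal(0.02) for linear
and attention weights, fan-in scaled normal for convolutions, ones/zeros for
normalization.  Every constructor takes an explicit ``rng`` so model builds
are reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "ModuleList",
    "Parameter",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Identity",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +-2 std, the transformer-weight default."""
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Module:
    """Minimal parameter container with named traversal."""

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "",
                         _seen: Optional[set] = None) -> Iterator[Tuple[str, Parameter]]:
        """Yield (name, parameter); parameters shared between submodules are
        yielded once, under the first path that reaches them."""
        if _seen is None:
            _seen = set()
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                if id(value) not in _seen:
                    _seen.add(id(value))
                    yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".", _seen=_seen)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(
                            prefix=f"{full}.{i}.", _seen=_seen
                        )
                    elif isinstance(item, Parameter):
                        if id(item) not in _seen:
                            _seen.add(id(item))
                            yield f"{full}.{i}", item

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch for keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *modules):
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """2-D convolution via im2col; weight layout (C_out, C_in, kh, kw)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0,
                 rng: Optional[np.random.Generator] = None,
                 bias: bool = True, zero_init: bool = False):
        rng = rng or np.random.default_rng()
        k = kernel_size
        if zero_init:
            w = np.zeros((out_ch, in_ch, k, k), dtype=np.float32)
        else:
            fan_in = in_ch * k * k
            w = (rng.standard_normal((out_ch, in_ch, k, k))
                 * math.sqrt(2.0 / fan_in)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel_size = k
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, s, p = self.kernel_size, self.stride, self.padding
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = x.im2col(k, k, s, p)                      # (B, C*k*k, Ho*Wo)
        wm = self.weight.reshape(self.out_ch, C * k * k)  # (Cout, C*k*k)
        y = wm @ cols                                     # (B, Cout, Ho*Wo)
        if self.bias is not None:
            y = y + self.bias.reshape(1, self.out_ch, 1)
        return y.reshape(B, self.out_ch, Ho, Wo)


class LayerNorm(Module):
    """Normalization over the trailing axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.weight + self.bias
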