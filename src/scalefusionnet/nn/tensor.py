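"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` together with a gradient
buffer and a closure that back-propagates into its parents.  The op set is the
minimum a windowed-attention segmentation network needs: broadcasting
arithmetic, batched matmul, reshaping/indexing, reductions, the usual
activations, and an ``im2col`` primitive on which convolution is built.

Multiply–accumulate operations (MACs) of every matmul can be recorded with
:func:`count_macs`; convolutions and attention products are matmuls
internally, so one counter covers the whole 1 MAC = 1 FLOP convention.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "count_macs",
    "no_grad",
    "stack",
]

_GRAD_ENABLED = True


class _MacCounter:
    def __init__(self) -> None:
        self.macs = 0


_MAC_COUNTER: Optional[_MacCounter] = None


@contextlib.contextmanager
def count_macs():
    """Context manager yielding a counter of matmul multiply–accumulates."""
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    counter = _MacCounter()
    _MAC_COUNTER = counter
    try:
        yield counter
    finally:
        _MAC_COUNTER = prev


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (a broadcast result) back to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: incoming buffers may alias a child's grad or a view
            self.grad = np.array(grad, dtype=np.float32)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS; networks here are deep enough to overflow recursion
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            if node is not self:
                node._backward = None
                node._parents = ()

    # --------------------------------------------------------------- helpers
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to(g, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        data = -self.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _sum_to(-g * self.data / (other.data ** 2), other.shape)
                )

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = np.matmul(self.data, other.data)
        if _MAC_COUNTER is not None:
            # batch dims x (n, k) @ (k, m)
            batch = int(np.prod(data.shape[:-2])) if data.ndim > 2 else 1
            k = self.data.shape[-1]
            _MAC_COUNTER.macs += batch * data.shape[-2] * data.shape[-1] * k

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_sum_to(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_sum_to(gb, other.shape))

        return Tensor._make(data, (self, other), backward)

    # ------------------------------------------------------------- structure
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        src_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]
        items = idx if isinstance(idx, tuple) else (idx,)
        basic = all(
            isinstance(i, (slice, int)) or i is None or i is Ellipsis
            for i in items
        )

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                if basic:  # basic indexing never repeats elements
                    self.grad[idx] += g
                else:
                    np.add.at(self.grad, idx, g)

        return Tensor._make(data, (self,), backward)

    def pad2d(self, top: int, bottom: int, left: int, right: int,
              axes: Tuple[int, int] = (-2, -1)) -> "Tensor":
        """Zero-pad two axes (default the trailing spatial pair)."""
        if top == bottom == left == right == 0:
            return self
        ay = axes[0] % self.ndim
        ax = axes[1] % self.ndim
        width = [(0, 0)] * self.ndim
        width[ay] = (top, bottom)
        width[ax] = (left, right)
        data = np.pad(self.data, width)
        H, W = self.shape[ay], self.shape[ax]

        def backward(g):
            if self.requires_grad:
                sl = [slice(None)] * self.ndim
                sl[ay] = slice(top, top + H)
                sl[ax] = slice(left, left + W)
                self._accumulate(g[tuple(sl)])

        return Tensor._make(data, (self,), backward)

    def roll(self, shifts: Sequence[int], axes: Sequence[int]) -> "Tensor":
        data = np.roll(self.data, shifts, axis=tuple(axes))
        neg = tuple(-s for s in shifts)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.roll(g, neg, axis=tuple(axes)))

        return Tensor._make(data, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.full_like(self.data, 1.0) * g)
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=keepdims)
        arg = self.data.argmax(axis=axis)

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                gg = g if keepdims else np.expand_dims(g, axis)
                np.put_along_axis(
                    grad, np.expand_dims(arg, axis), gg, axis=axis
                )
                self._accumulate(grad)

        return Tensor._make(data, (self,), backward)

    # ----------------------------------------------------------- activations
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def sigmoid(self) -> "Tensor":
        data = _special.expit(self.data).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def gelu(self) -> "Tensor":
        """Exact (erf-based) GELU."""
        x = self.data
        phi = 0.5 * (1.0 + _special.erf(x / math.sqrt(2.0)))
        data = (x * phi).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accumulate((g * (phi + x * pdf)).astype(np.float32))

        return Tensor._make(data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * data).sum(axis=axis, keepdims=True)
                self._accumulate(data * (g - dot))

        return Tensor._make(data.astype(np.float32), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(data, (self,), backward)

    # --------------------------------------------------------- convolutional
    def im2col(self, kh: int, kw: int, stride: int, pad: int) -> "Tensor":
        """Unfold (B, C, H, W) into (B, C*kh*kw, Ho*Wo) patches."""
        B, C, H, W = self.shape
        xp = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Ho = (H + 2 * pad - kh) // stride + 1
        Wo = (W + 2 * pad - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, Ho * Wo)
        cols = np.ascontiguousarray(cols)

        def backward(g):
            if self.requires_grad:
                g6 = g.reshape(B, C, kh, kw, Ho, Wo)
                gp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gp[
                            :, :, i : i + Ho * stride : stride,
                            j : j + Wo * stride : stride,
                        ] += g6[:, :, i, j]
                if pad:
                    gp = gp[:, :, pad : pad + H, pad : pad + W]
                self._accumulate(gp)

        return Tensor._make(cols, (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(data, tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(np.squeeze(p, axis=axis))

    return Tensor._make(data, tensors, backward)
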