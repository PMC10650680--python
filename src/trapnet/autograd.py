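"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective implemented by this package mixes standard
differentiable pieces (convolutions, attention, cross-entropy) with
non-standard gradient semantics: a gradient reversal layer, focal weights
that are excluded from the gradient, and a correlation-alignment term whose
backward pass is an analytic formula.  A small tape-based autodiff engine
keeps all of these in one graph and makes every gradient checkable by
central finite differences.

Only the operations the package needs are provided.  Tensors wrap numpy
arrays of any dtype; float64 is convenient for gradient checks, float32 for
training speed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d3x3",
    "gather_rows",
    "grl",
    "logsumexp",
    "matmul",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make `ndarray <op> Tensor` defer to the Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def __len__(self) -> int:
        return len(self.data)

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- helpers -------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _node(self, data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data**2))

        return self._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("tensor exponents are not supported")
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, self._lift(other))

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, negative_slope).astype(self.data.dtype)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * scale)

        return self._node(self.data * scale, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sig)

        return self._node(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only where not clipped."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._node(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.asarray(g).reshape(orig))

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.asarray(g).transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, np.asarray(g))
                self._accumulate(full)

        return self._node(out_data, (self,), backward)


# -- free functions -----------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product supporting batched (stacked) operands."""
    out_data = a.data @ b.data

    def backward(g):
        g = np.asarray(g)
        if a.requires_grad:
            ga = g @ b.data.swapaxes(-1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return a._node(out_data, (a, b), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    if any(t.data.size == 0 for t in tensors):
        raise ValueError("cannot concatenate empty tensors")
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(np.asarray(g), splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return tensors[0]._node(out_data, tuple(tensors), backward)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-sum-exp along `axis` (keeps the axis collapsed)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = np.exp(x.data - m)
    total = shifted.sum(axis=axis)
    out_data = np.squeeze(m, axis=axis) + np.log(total)
    soft = shifted / np.expand_dims(total, axis)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.expand_dims(np.asarray(g), axis) * soft)

    return x._node(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            g = np.asarray(g)
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - dot))

    return x._node(out_data, (x,), backward)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select x[i, index[i]] for every row i of a 2-D tensor."""
    index = np.asarray(index)
    rows = np.arange(x.data.shape[0])
    out_data = x.data[rows, index]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (rows, index), np.asarray(g))
            x._accumulate(full)

    return x._node(out_data, (x,), backward)


def grl(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by -lam backward."""
    if lam < 0:
        raise ValueError("gradient reversal coefficient must be >= 0")

    def backward(g):
        if x.requires_grad:
            x._accumulate(-lam * np.asarray(g))

    return x._node(x.data, (x,), backward)


def conv2d3x3(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3x3 convolution with padding 1, NCHW layout, via im2col matmul.

    x: (B, C, H, W); w: (C_out, C, 3, 3); b: (C_out,).
    """
    B, C, H, W = x.data.shape
    c_out = w.data.shape[0]
    if w.data.shape[1] != C:
        raise ValueError(f"weight expects {w.data.shape[1]} input channels, got {C}")
    ho = (H + 2 - 3) // stride + 1
    wo = (W + 2 - 3) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((B, ho, wo, C, 9), dtype=x.data.dtype)
    for ki in range(3):
        for kj in range(3):
            patch = xp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride]
            cols[..., ki * 3 + kj] = patch.transpose(0, 2, 3, 1)
    col2 = cols.reshape(B * ho * wo, C * 9)
    w2 = w.data.reshape(c_out, C * 9)
    out = col2 @ w2.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(B, ho, wo, c_out).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = np.asarray(g).transpose(0, 2, 3, 1).reshape(B * ho * wo, c_out)
        if w.requires_grad:
            w._accumulate((g2.T @ col2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcol = (g2 @ w2).reshape(B, ho, wo, C, 9)
            dxp = np.zeros_like(xp)
            for ki in range(3):
                for kj in range(3):
                    dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += dcol[
                        ..., ki * 3 + kj
                    ].transpose(0, 3, 1, 2)
            x._accumulate(dxp[:, :, 1:-1, 1:-1])

    return x._node(out_data, parents, backward)
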