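"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the surrogate architectures
need: broadcast arithmetic, matmul, ELU/ReLU, reductions, gather /
segment-sum for message passing on graphs, and strided 2-D convolution
via im2col.  Gradients are accumulated in float64 throughout; there is no
device abstraction and no graph retention after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g, out):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._make(self.data @ other.data, (self, other), bw)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        ex = np.where(neg, np.exp(np.minimum(self.data, 0.0)), 1.0)
        val = np.where(neg, alpha * (ex - 1.0), self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * np.where(neg, alpha * ex, 1.0))

        return self._make(val, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        fac = np.where(self.data > 0, 1.0, slope)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * fac)

        return self._make(self.data * fac, (self,), bw)

    def abs(self):
        s = np.sign(self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * s)

        return self._make(np.abs(self.data), (self,), bw)

    def exp(self):
        val = np.exp(self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * val)

        return self._make(val, (self,), bw)

    def log(self):
        def bw(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max-reduction along one axis; ties send gradient to the first hit."""
        idx = np.argmax(self.data, axis=axis)
        val = np.max(self.data, axis=axis)

        def bw(g, out):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            self._accum(full)

        return self._make(val, (self,), bw)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def gather(self, index: np.ndarray):
        """Select rows (axis 0); backward scatter-adds."""
        index = np.asarray(index)

        def bw(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        return self._make(self.data[index], (self,), bw)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Sum rows into `num_segments` buckets; backward gathers."""
        segment_ids = np.asarray(segment_ids)
        out_data = np.zeros((num_segments,) + self.data.shape[1:])
        np.add.at(out_data, segment_ids, self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g[segment_ids])

        return self._make(out_data, (self,), bw)

    # -- backward driver -----------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad, t)
        # free the graph
        for t in topo:
            t._backward = None
            t._parents = ()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g, _):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    expanded = [t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) for t in tensors]
    return concat(expanded, axis=axis)
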