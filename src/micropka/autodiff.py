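"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the graph models need: dense linear algebra,
broadcasting elementwise arithmetic, a few activations, masked softmax,
reductions and concatenation.  Gradients flow to any tensor created with
``requires_grad=True``, including model *inputs*, which is what the
integrated-gradients attribution requires.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


class _NoGrad:
    """Context manager that disables graph construction (inference mode)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and not _NoGrad._active
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents) and not _NoGrad._active
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- properties -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self):
        def bw(g):
            self._accum(g.T)

        return Tensor._make(self.data.T, (self,), bw)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    # -- activations ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor._make(out, (self,), bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out**2))

        return Tensor._make(out, (self,), bw)

    def exp(self):
        out = np.exp(np.clip(self.data, -700, 700))

        def bw(g):
            self._accum(g * out)

        return Tensor._make(out, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis` (max-shift is constant)."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accum(out * (g - dot))

        return Tensor._make(out, (self,), bw)

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        def bw(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), bw)
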