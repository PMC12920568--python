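"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
a backward closure.  Calling :meth:`Tensor.backward` on a scalar loss walks
the recorded graph in reverse topological order and accumulates gradients
into every tensor created with ``requires_grad=True``.

Only the operations the gene/peptide models need are implemented; each op
states its backward rule explicitly rather than relying on a generic vjp
machinery, which keeps the engine small and auditable.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, dtype=None, _prev=()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype if dtype is not None else None)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = Tensor(self.data + other.data, _prev=self._track(other))
        if out._prev:
            def bw(g):
                if self.requires_grad or self._prev:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad or other._prev:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = Tensor(self.data * other.data, _prev=self._track(other))
        if out._prev:
            def bw(g):
                if self.requires_grad or self._prev:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad or other._prev:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.pow(-1.0)
        return self * (1.0 / float(other))

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g * p * self.data ** (p - 1.0))
            out._backward = bw
        return out

    def _track(self, *others):
        prev = []
        for t in (self,) + others:
            if t.requires_grad or t._prev:
                prev.append(t)
        return tuple(prev)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(np.matmul(self.data, other.data), _prev=self._track(other))
        if out._prev:
            def bw(g):
                if self.requires_grad or self._prev:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad or other._prev:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g.reshape(old))
            out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g.transpose(inv))
            out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=self._track())
        if out._prev:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=self._track())
        if out._prev:
            shape = self.shape

            def bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, shape).copy())
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(g, shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=self._track())
        if out._prev:
            mask = self.data > 0

            def bw(g):
                self._accum(g * mask)
            out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g * s * (1.0 - s))
            out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g * (1.0 - t * t))
            out._backward = bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g * e)
            out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=self._track())
        if out._prev:
            def bw(g):
                self._accum(g / self.data)
            out._backward = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=self._track())
        if out._prev:
            def bw(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
            out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    prev = tuple(t for t in tensors if t.requires_grad or t._prev)
    out = Tensor(out_data, _prev=prev)
    if prev:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad or t._prev:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)
    prev = tuple(t for t in tensors if t.requires_grad or t._prev)
    out = Tensor(out_data, _prev=prev)
    if prev:
        def bw(g):
            parts = np.moveaxis(g, axis, 0)
            for t, gt in zip(tensors, parts):
                if t.requires_grad or t._prev:
                    t._accum(gt)
        out._backward = bw
    return out


def binary_cross_entropy(p: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean BCE between predicted probabilities and 0/1 targets."""
    t = np.asarray(target, dtype=p.dtype).reshape(p.shape)
    pc = np.clip(p.data, eps, 1.0 - eps)
    loss_val = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean()
    out = Tensor(loss_val, _prev=p._track())
    if out._prev:
        def bw(g):
            grad = (pc - t) / (pc * (1.0 - pc)) / t.size
            p._accum(g * grad)
        out._backward = bw
    return out
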