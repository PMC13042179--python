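"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the tabular encoders need: broadcasted
arithmetic, batched matmul, relu/exp/log/power, reductions, reshape /
transpose / slicing / concatenation, and a fused last-axis softmax.
Gradients are accumulated by a topological-order sweep.  The engine
preserves the input dtype, so float64 gradient checking and float32
training use the same code path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "softmax_lastdim"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))
        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))
        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __pow__(self, p: float):
        d = self.data

        def backward(g):
            return (g * p * d ** (p - 1.0),)
        return Tensor._make(d ** p, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)
        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)
        return Tensor._make(np.log(self.data), (self,), backward)

    def __matmul__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))
        return Tensor._make(out_data, (a, b), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)
        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)
        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(*inv),)
        return Tensor._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, key):
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, key, g)
            return (full,)
        return Tensor._make(self.data[key], (self,), backward)

    def broadcast_to(self, shape):
        old = self.data.shape

        def backward(g):
            return (_unbroadcast(g, old),)
        return Tensor._make(np.broadcast_to(self.data, shape), (self,), backward)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)

        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self):
        self.grad = None


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        return (g * mask,)
    return Tensor._make(x.data * mask, (x,), backward)


def softmax_lastdim(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        return (s * (g - dot),)
    return Tensor._make(s, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._make(out_data, tuple(tensors), backward)
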