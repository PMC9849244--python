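"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float32 ndarray and
records, for every differentiable operation, a closure that routes the
upstream gradient to its parents.  ``Tensor.backward()`` runs the closures in
reverse topological order.  Only the operations the segmentation network
actually needs are implemented; convolution, pooling, resizing and batch
normalisation live in :mod:`slhardnet.nn.ops`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat", "softmax"]

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo = _postorder(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- shape attributes --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        a, b = self, _wrap(other)

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, _wrap(other)

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _wrap(other)

        def back(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def back(g):
            a._accumulate(g * p * np.power(a.data, p - 1))

        return Tensor._make(np.power(a.data, p), (a,), back)

    # -- unary functions ---------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def back(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), back)

    def log(self):
        a = self

        def back(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), back)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def back(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), back)

    def abs(self):
        a = self

        def back(g):
            a._accumulate(g * np.sign(a.data))

        return Tensor._make(np.abs(a.data), (a,), back)

    def relu(self):
        a = self
        mask = a.data > 0

        def back(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), back)

    def sigmoid(self):
        a = self
        # numerically stable two-sided formulation
        s = np.empty_like(a.data)
        pos = a.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
        ex = np.exp(a.data[~pos])
        s[~pos] = ex / (1.0 + ex)

        def back(g):
            a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), back)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

        def back(g):
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            buf = np.zeros_like(a.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), gg, axis=axis)
            a._accumulate(buf)

        out = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(out, (a,), back)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def back(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def back(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), back)

    def __getitem__(self, key):
        a = self

        def back(g):
            buf = np.zeros_like(a.data)
            np.add.at(buf, key, g)
            a._accumulate(buf)

        return Tensor._make(a.data[key], (a,), back)

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        a, b = self, _wrap(other)

        def back(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), back)

    def __rmatmul__(self, other):
        return _wrap(other) @ self


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _axis_size(shape, axis):
    if isinstance(axis, int):
        return shape[axis]
    n = 1
    for ax in axis:
        n *= shape[ax]
    return n


def _postorder(root: Tensor) -> list:
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


# -- free functions --------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tensors, back)


def softmax(x: Tensor, axis: int) -> Tensor:
    a = x
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        a._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor._make(s, (a,), back)
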