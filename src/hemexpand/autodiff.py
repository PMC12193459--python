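"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-free define-by-run engine: every operation builds a node holding its
parents and a closure that maps the output gradient to parent gradients.
``Tensor.backward()`` topologically sorts the graph and accumulates gradients
into ``.grad``. Only the primitives needed by the sequence model live here
(broadcast arithmetic, batched matmul, reductions, exp/log/sqrt, softplus,
tanh, relu, reshape/transpose/concat). Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source operand."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with optional gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph management --------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitives ------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return ((a, _sum_to_shape(g, a.shape)), (b, _sum_to_shape(g, b.shape)))

    return _node(a.data + b.data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return (
            (a, _sum_to_shape(g * b.data, a.shape)),
            (b, _sum_to_shape(g * a.data, b.shape)),
        )

    return _node(a.data * b.data, (a, b), backward)


def power(a, exponent: float):
    a = _wrap(a)
    e = float(exponent)

    def backward(g):
        return ((a, _sum_to_shape(g * e * np.power(a.data, e - 1.0), a.shape)),)

    return _node(np.power(a.data, e), (a,), backward)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        ga = g @ b.data.swapaxes(-1, -2)
        gb = a.data.swapaxes(-1, -2) @ g
        return ((a, _sum_to_shape(ga, a.shape)), (b, _sum_to_shape(gb, b.shape)))

    return _node(a.data @ b.data, (a, b), backward)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        return ((a, g * out_data),)

    return _node(out_data, (a,), backward)


def log(a):
    a = _wrap(a)

    def backward(g):
        return ((a, g / a.data),)

    return _node(np.log(a.data), (a,), backward)


def sqrt(a):
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        return ((a, g * 0.5 / out_data),)

    return _node(out_data, (a,), backward)


def softplus(a):
    """log(1 + exp(x)) computed stably; derivative is the logistic sigmoid."""
    a = _wrap(a)

    def backward(g):
        return ((a, g * expit(a.data)),)

    return _node(np.logaddexp(0.0, a.data), (a,), backward)


def tanh(a):
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        return ((a, g * (1.0 - out_data**2)),)

    return _node(out_data, (a,), backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        return ((a, g * mask),)

    return _node(np.where(mask, a.data, 0.0), (a,), backward)


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.shape).copy()),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.shape).copy()),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = _wrap(a)

    def backward(g):
        return ((a, g.reshape(a.shape)),)

    return _node(a.data.reshape(shape), (a,), backward)


def swapaxes(a, ax1, ax2):
    a = _wrap(a)

    def backward(g):
        return ((a, g.swapaxes(ax1, ax2)),)

    return _node(a.data.swapaxes(ax1, ax2), (a,), backward)


def concat(tensors, axis=-1):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def softmax(a, axis=-1):
    """Numerically stable softmax; the max shift is a constant w.r.t. grads."""
    a = _wrap(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return e / tsum(e, axis=axis, keepdims=True)
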