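"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: matrix products,
broadcast add/multiply, tanh and leaky-rectifier nonlinearities,
concatenation, masked row softmax, summation, and elementwise powers.
Gradients are accumulated by a topological-order sweep over the tape,
micrograd-style. Every op is checked against central finite differences
in the test suite.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "parameter", "concat", "masked_row_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators instead of broadcasting
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction -------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def leaky_relu(self, slope: float = 0.2):
        y = np.where(self.data > 0, self.data, slope * self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * np.where(self.data > 0, 1.0, slope),)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def pow(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def square(self):
        out = Tensor(self.data ** 2, parents=(self,))
        out._backward = lambda g: (2.0 * g * self.data,)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: (np.broadcast_to(g, self.shape).copy(),)
        return out

    def mean_axis0(self):
        n = self.shape[0]
        out = Tensor(self.data.mean(axis=0), parents=(self,))
        out._backward = lambda g: (np.broadcast_to(g / n, self.shape).copy(),)
        return out

    # ---- backward sweep -----------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or not t.requires_grad:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


def masked_row_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to `mask` (boolean); masked-out entries are 0.

    Every row must have at least one admissible entry. Overflow-safe via
    per-row max subtraction over the admissible set.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("masked_row_softmax: a row has an empty neighborhood")
    z = np.where(mask, logits.data, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = Tensor(p, parents=(logits,))

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    out._backward = backward
    return out


class Adam:
    """Adaptive-moment-estimation optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient encountered")
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
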