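"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the small conditional-VAE used for
harmonization: dense layers, tanh, the Gaussian KL term, an RBF-kernel MMD,
and a softmax cross-entropy — all expressible with the primitives below.
Gradients propagate through numpy broadcasting; ``Adam`` is the only
optimizer provided.  Everything is deterministic given the caller's RNG.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._backward = lambda: None
        self._prev = _prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- primitives ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))
        out._backward = backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = backward
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** (-1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))
        out._backward = backward
        return out

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.T)
        out._backward = backward
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1 - t * t))
        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * e)
        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = backward
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def logsumexp(self, axis=1):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        out = Tensor((m + np.log(s)).squeeze(axis), _prev=(self,))

        def backward():
            if self.requires_grad:
                soft = np.exp(self.data - m) / s
                self._accum(np.expand_dims(out.grad, axis) * soft)
        out._backward = backward
        return out

    def detach(self):
        return Tensor(self.data.copy())

    # -- graph traversal ----------------------------------------------------
    def backward(self):
        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._prev:
                visit(p)
            order.append(node)
        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.requires_grad:
                node._backward()


def concat(tensors, axis=1):
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])
    out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; `labels` are integer class indices."""
    n = logits.shape[0]
    picked = (logits * Tensor(np.eye(logits.shape[1])[labels])).sum(axis=1)
    return (logits.logsumexp(axis=1) - picked).mean()


def rbf_mmd2(x: Tensor, y: Tensor, bandwidth: float) -> Tensor:
    """Squared MMD (biased V-statistic) with an RBF kernel of width h.

    The bandwidth is treated as a constant (compute it from detached data)."""
    h2 = 2.0 * bandwidth * bandwidth

    def gram(a: Tensor, b: Tensor) -> Tensor:
        a2 = (a * a).sum(axis=1, keepdims=True)          # (n,1)
        b2 = (b * b).sum(axis=1, keepdims=True)          # (m,1)
        d2 = a2 + b2.T - (a @ b.T) * 2.0
        return (d2 * (-1.0 / h2)).exp()

    return gram(x, x).mean() + gram(y, y).mean() - gram(x, y).mean() * 2.0


class Linear:
    """Dense layer with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
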