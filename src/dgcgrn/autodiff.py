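"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable pieces of the pipeline (directed graph convolution layers, the
CVAE feature generator, the Bi-GRU sequence encoder and the edge-scoring head)
are all compositions of dense linear maps, elementwise nonlinearities,
embedding lookups and reductions.  This module provides exactly that operator
set on a :class:`Tensor` wrapper, plus Glorot initialisation and an Adam
optimiser.  Everything is float64 and deterministic given the numpy
``Generator`` objects passed in by callers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "embedding",
    "rows",
    "col_slice",
    "glorot",
    "Linear",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise / linear algebra -------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * -1.0)

    def __rsub__(self, other):
        return Tensor(other) + (self * -1.0)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.reciprocal()
        return self * (1.0 / other)

    def reciprocal(self):
        out = Tensor(1.0 / self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g / (self.data ** 2))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - val ** 2))

        out._backward = _bw
        return out

    def sigmoid(self):
        val = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor(val, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = _bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _bw
        return out

    def softplus(self):
        """log(1 + exp(x)), stable; gradient is sigmoid(x)."""
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 * (1.0 + np.tanh(0.5 * self.data)))

        out._backward = _bw
        return out

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``; gradient splits back."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = _bw
    return out


def rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Integer-array row gather ``t[idx]``; gradient scatter-adds."""
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], t.requires_grad, (t,))

    def _bw(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accumulate(full)

    out._backward = _bw
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: identical to one-hot(ids) @ weight."""
    return rows(weight, ids)


def col_slice(t: Tensor, start: int, stop: int) -> Tensor:
    """Slice columns [start, stop) of a 2-D tensor."""
    out = Tensor(t.data[:, start:stop], t.requires_grad, (t,))

    def _bw(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[:, start:stop] = g
            t._accumulate(full)

    out._backward = _bw
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    """Dense affine layer ``x @ W + b``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
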