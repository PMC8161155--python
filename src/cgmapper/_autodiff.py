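"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the message-passing network:
broadcast add/mul, matmul, pointwise nonlinearities, row gathering,
column concatenation and reductions.  Float64 throughout; gradients are
accumulated by reverse topological sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn")

    def __init__(self, data, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers --------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out.backward_fn = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out.backward_fn = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out.backward_fn = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            return g @ other.data.T, self.data.T @ g

        out.backward_fn = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out.backward_fn = lambda g: (g * s * (1.0 - s),)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out.backward_fn = lambda g: (g * (1.0 - t * t),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out.backward_fn = lambda g: (g * mask,)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(shape), (self,))
        out.backward_fn = lambda g: (g.reshape(self.shape),)
        return out

    def rows(self, index) -> "Tensor":
        """Gather rows by integer index; backward scatter-adds."""
        index = np.asarray(index, dtype=int)
        out = Tensor(self.data[index], (self,))

        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, index, g)
            return (gx,)

        out.backward_fn = bwd
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))
        out.backward_fn = lambda g: (np.broadcast_to(g, self.shape).copy(),)
        return out

    def sumsq_rows(self) -> "Tensor":
        """Row-wise sum of squares, shape (n, 1)."""
        out = Tensor((self.data**2).sum(axis=1, keepdims=True), (self,))
        out.backward_fn = lambda g: (2.0 * g * self.data,)
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r, (self,))
        out.backward_fn = lambda g: (g * 0.5 / r,)
        return out

    def reciprocal(self) -> "Tensor":
        inv = 1.0 / self.data
        out = Tensor(inv, (self,))
        out.backward_fn = lambda g: (-g * inv * inv,)
        return out

    # -- backward pass ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order DFS
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.backward_fn(node.grad)):
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def concat_cols(tensors) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors))
    widths = [t.data.shape[1] for t in tensors]
    splits = np.cumsum(widths)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=1))

    out.backward_fn = bwd
    return out


def normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """L2-normalize each row; rows of norm < eps are guarded, not divided by 0."""
    norm = (x.sumsq_rows() + eps).sqrt()
    return x * norm.reciprocal()


def mean_all(x: Tensor) -> Tensor:
    return x.sum() * (1.0 / x.data.size)


class Adam:
    """Adam optimizer over a flat dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            v = self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
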