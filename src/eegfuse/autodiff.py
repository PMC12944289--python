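"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides the small set of differentiable operations the model needs:
broadcast arithmetic, batched matmul, shape manipulation, pointwise
nonlinearities, reductions, softmax and gather.  Tensors form a DAG;
``backward()`` runs a topological sweep accumulating gradients into
every tensor created with ``requires_grad=True``.

Everything is float64.  The engine is deliberately tiny: no in-place
ops, no views that alias, no higher-order gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "softmax",
    "gather",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires scalar output")
            grad = np.ones_like(self.data)
        # topological order
        order, seen = [], set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            order.append(node)
            stack.extend(node._parents)
        # Kahn-free: sort by discovery is not topological; do DFS post-order
        order, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 100000))
        try:
            visit(self)
        finally:
            sys.setrecursionlimit(old)

        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            return [
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ]

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            return [
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ]

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            return [
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ]

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            return [(self, g * p * self.data ** (p - 1))]

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def bw(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return [
                (self, _unbroadcast(ga, a.shape)),
                (other, _unbroadcast(gb, b.shape)),
            ]

        return self._make(np.matmul(a, b), (self, other), bw)

    # --------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            return [(self, g.reshape(old))]

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            return [(self, g.transpose(inv))]

        return self._make(self.data.transpose(axes), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            return [(self, g.swapaxes(a, b))]

        return self._make(self.data.swapaxes(a, b), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return [(self, full)]

        return self._make(self.data[idx], (self,), bw)

    # ------------------------------------------------------------ pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return [(self, g * out_data)]

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            return [(self, g / self.data)]

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            return [(self, g * (1.0 - out_data**2))]

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            return [(self, g * out_data * (1.0 - out_data))]

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            return [(self, g * mask)]

        return self._make(self.data * mask, (self,), bw)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_part = alpha * (np.exp(np.minimum(self.data, 0)) - 1.0)
        out_data = np.where(pos, self.data, neg_part)

        def bw(g):
            return [(self, g * np.where(pos, 1.0, neg_part + alpha))]

        return self._make(out_data, (self,), bw)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.shape).copy())]
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return [(self, np.broadcast_to(gg, self.shape).copy())]

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ------------------------------------------------------------------ helpers
def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        return [(t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts)]

    return Tensor._make(data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant w.r.t. the gradient
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax restricted to entries where ``mask`` is truthy.

    Excluded positions get exactly zero weight; every row must contain at
    least one admitted entry.
    """
    mask = np.asarray(mask, dtype=np.float64)
    neg = Tensor((1.0 - mask) * -1e30)
    shifted = x * Tensor(mask) + neg
    shift = Tensor(shifted.data.max(axis=axis, keepdims=True))
    e = (shifted - shift).exp() * Tensor(mask)
    return e / e.sum(axis=axis, keepdims=True)


def gather(probs: Tensor, index: np.ndarray) -> Tensor:
    """Select probs[i, index[i]] for each row i."""
    index = np.asarray(index, dtype=np.intp)
    rows = np.arange(probs.shape[0])

    def bw(g):
        full = np.zeros_like(probs.data)
        full[rows, index] = g
        return [(probs, full)]

    return Tensor._make(probs.data[rows, index], (probs,), bw)


def cross_entropy(probs: Tensor, labels: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under `probs`."""
    picked = gather(probs, labels)
    return -((picked + eps).log()).mean()
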