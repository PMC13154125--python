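"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph networks need: broadcasted
elementwise arithmetic, matrix and batched matrix products, ReLU, row
gather / segment reduction (message passing and pooling), concatenation,
and a fused log-softmax cross-entropy loss. Gradients are accumulated by
topological-order backpropagation from a scalar loss.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node.parents:
                    stack.append((p, False))

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t.backward_fn is not None:
                t.backward_fn(t.grad)

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        out.backward_fn = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        out.backward_fn = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other).pow(-1.0)

    def pow(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bw(g):
            _accum(self, g * p * self.data ** (p - 1.0))

        out.backward_fn = bw
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            _accum(self, g @ other.data.T)
            _accum(other, self.data.T @ g)

        out.backward_fn = bw
        return out

    def bmm(self, other: "Tensor"):
        """Batched matmul: (B, n, k) @ (B, k, m) -> (B, n, m)."""
        out = Tensor(np.einsum("bnk,bkm->bnm", self.data, other.data), parents=(self, other))

        def bw(g):
            _accum(self, np.einsum("bnm,bkm->bnk", g, other.data))
            _accum(other, np.einsum("bnk,bnm->bkm", self.data, g))

        out.backward_fn = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out.backward_fn = lambda g: _accum(self, g * mask)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out.backward_fn = lambda g: _accum(self, g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accum(self, np.broadcast_to(gg, self.data.shape))

        out.backward_fn = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather_rows(self, index: np.ndarray):
        index = np.asarray(index, dtype=int)
        out = Tensor(self.data[index], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            _accum(self, acc)

        out.backward_fn = bw
        return out

    def segment_sum(self, segment_ids: np.ndarray, n_segments: int):
        segment_ids = np.asarray(segment_ids, dtype=int)
        acc = np.zeros((n_segments,) + self.data.shape[1:])
        np.add.at(acc, segment_ids, self.data)
        out = Tensor(acc, parents=(self,))
        out.backward_fn = lambda g: _accum(self, g[segment_ids])
        return out

    def segment_mean(self, segment_ids: np.ndarray, n_segments: int):
        counts = np.bincount(np.asarray(segment_ids, dtype=int), minlength=n_segments)
        counts = np.maximum(counts, 1).astype(float)
        summed = self.segment_sum(segment_ids, n_segments)
        return summed * (1.0 / counts)[(...,) + (None,) * (self.data.ndim - 1)]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad and t.grad is not None:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out.backward_fn = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    labels = np.asarray(labels, dtype=int)
    p = softmax(logits.data)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        _accum(logits, float(g) * grad / n)

    out.backward_fn = bw
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, grad_clip: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.grad_clip is not None:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if norm > self.grad_clip:
                scale = self.grad_clip / (norm + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
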