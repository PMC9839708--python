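"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the recurrent autoencoder needs (affine
maps, gating nonlinearities, attention, summed squared error) as nodes on a
tape, plus an Adam optimizer.  Gradients are accumulated in float64 and are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "matmul", "add", "mul", "sub", "one_minus",
           "sigmoid", "tanh", "concat", "stack", "attention", "sse", "scale"]


class Tensor:
    """A node in the computation graph wrapping an ndarray value."""

    __slots__ = ("value", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward_fn=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) node."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative post-order topological sort (graphs can be deep: T ~ 100 steps)
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node.parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                order.append(node)
                stack_.pop()
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g


def _node(value, parents, backward_fn) -> Tensor:
    t = Tensor(value, parents=parents, backward_fn=backward_fn)
    if not t.requires_grad:
        t.backward_fn = None
    return t


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value @ b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ g)

    return _node(out_val, (a, b), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise add; b may broadcast (bias row vector against a batch)."""
    out_val = a.value + b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.value.shape))

    return _node(out_val, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value - b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.value.shape))

    return _node(out_val, (a, b), bwd)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value * b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.value, b.value.shape))

    return _node(out_val, (a, b), bwd)


def one_minus(a: Tensor) -> Tensor:
    out_val = 1.0 - a.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _node(out_val, (a,), bwd)


def scale(a: Tensor, c: float) -> Tensor:
    out_val = a.value * c

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return _node(out_val, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out_val = 1.0 / (1.0 + np.exp(-a.value))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * out_val * (1.0 - out_val))

    return _node(out_val, (a,), bwd)


def tanh(a: Tensor) -> Tensor:
    out_val = np.tanh(a.value)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_val**2))

    return _node(out_val, (a,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _node(out_val, tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_val = np.stack([t.value for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return _node(out_val, tuple(tensors), bwd)


def attention(enc: Tensor, query: Tensor) -> tuple[Tensor, np.ndarray]:
    """Dot-product attention of a query (B, H) over encoder states (B, T, H).

    Returns the context vector (B, H) and, for introspection, the softmax
    weight matrix (B, T) as a plain array.
    """
    E, h = enc.value, query.value
    scores = np.einsum("bth,bh->bt", E, h)
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    ctx = np.einsum("bt,bth->bh", w, E)

    def bwd(g):
        dw = np.einsum("bth,bh->bt", E, g)
        ds = w * (dw - np.einsum("bt,bt->b", w, dw)[:, None])
        if enc.requires_grad:
            dE = w[:, :, None] * g[:, None, :] + ds[:, :, None] * h[:, None, :]
            enc._accumulate(dE)
        if query.requires_grad:
            query._accumulate(np.einsum("bt,bth->bh", ds, E))

    return _node(ctx, (enc, query), bwd), w


def matvec_last(a: Tensor, v: Tensor) -> Tensor:
    """(B, T, H) x (H, 1) -> (B, T): inner product along the trailing axis."""
    out_val = np.einsum("bth,h->bt", a.value, v.value[:, 0])

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[:, :, None] * v.value[:, 0][None, None, :])
        if v.requires_grad:
            v._accumulate(np.einsum("bt,bth->h", g, a.value)[:, None])

    return _node(out_val, (a, v), bwd)


def softmax_context(values: Tensor, scores: Tensor) -> tuple[Tensor, np.ndarray]:
    """Softmax the scores (B, T) over T and take the weighted sum of values (B, T, H).

    Returns the context (B, H) and the weights (B, T) as a plain array.
    """
    V, s = values.value, scores.value
    s = s - s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)
    ctx = np.einsum("bt,bth->bh", w, V)

    def bwd(g):
        dw = np.einsum("bth,bh->bt", V, g)
        ds = w * (dw - np.einsum("bt,bt->b", w, dw)[:, None])
        if values.requires_grad:
            values._accumulate(w[:, :, None] * g[:, None, :])
        if scores.requires_grad:
            scores._accumulate(ds)

    return _node(ctx, (values, scores), bwd), w


def sse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Sum of squared errors against a constant target."""
    diff = pred.value - target
    out_val = np.array(np.sum(diff * diff))

    def bwd(g):
        if pred.requires_grad:
            pred._accumulate(2.0 * g * diff)

    return _node(out_val, (pred,), bwd)


class Adam:
    """Adaptive-moment-estimation gradient descent over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
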