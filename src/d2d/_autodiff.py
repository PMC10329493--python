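"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the sequence models need: broadcasting
arithmetic, (batched) matmul, embedding lookup, layer normalization, softmax /
log-softmax with fused vector-Jacobian products, gather, stack and axis
reductions — plus an Adam optimizer.  Gradients are accumulated on a dynamic
tape; ``no_grad()`` disables tape construction for inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- conveniences -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        if not isinstance(other, Tensor):
            o = np.asarray(other, dtype=self.data.dtype)
            out_data = self.data + o

            def back(g):
                self._accum(_unbroadcast(g, self.data.shape))
            return Tensor._make(out_data, (self,), back)
        out_data = self.data + other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        if isinstance(other, Tensor):
            return self + (-other)
        return self + (-np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            o = np.asarray(other, dtype=self.data.dtype)
            out_data = self.data * o

            def back(g):
                self._accum(_unbroadcast(g * o, self.data.shape))
            return Tensor._make(out_data, (self,), back)
        out_data = self.data * other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("tensor/tensor division not needed")
        return self * (1.0 / np.asarray(other))

    def __matmul__(self, other):
        a, b = self.data, other.data
        out_data = a @ b

        def back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))
        return Tensor._make(out_data, (self, other), back)

    # -- shaping ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def back(g):
            self._accum(g.reshape(old))
        return Tensor._make(out_data, (self,), back)

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)

        def back(g):
            self._accum(np.swapaxes(g, a, b))
        return Tensor._make(out_data, (self,), back)

    def __getitem__(self, key):
        out_data = self.data[key]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)
        return Tensor._make(out_data, (self,), back)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def back(g):
            self._accum(g * mask)
        return Tensor._make(out_data, (self,), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accum(g * out_data)
        return Tensor._make(out_data, (self,), back)


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))
    return Tensor._make(s, (x,), back)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    s = np.exp(out_data)

    def back(g):
        x._accum(g - s * g.sum(axis=axis, keepdims=True))
    return Tensor._make(out_data, (x,), back)


def embedding(W: Tensor, idx: np.ndarray) -> Tensor:
    out_data = W.data[idx]

    def back(g):
        dW = np.zeros_like(W.data)
        np.add.at(dW, idx, g)
        W._accum(dW)
    return Tensor._make(out_data, (W,), back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    n = x.data.shape[-1]

    def back(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx.mean(axis=-1, keepdims=True)
            t2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gx - t1 - xhat * t2))
    return Tensor._make(out_data, (x, gamma, beta), back)


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """``out[..., ] = x[..., idx[...]]`` along the last axis."""
    out_data = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]

    def back(g):
        full = np.zeros_like(x.data)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        x._accum(full)
    return Tensor._make(out_data, (x,), back)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))
    return Tensor._make(out_data, tuple(tensors), back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)
    return Tensor._make(out_data, tuple(tensors), back)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``p == 0`` or no generator is given."""
    if p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * mask


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters stay differentiable under no_grad


class Adam:
    """Standard Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr=5e-4, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
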