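"""Minimal reverse-mode automatic differentiation and neural-network layers.

A compact tensor/graph engine sufficient for the forecaster architecture used
in this package: dense layers, layer normalization, multi-head self-attention
and gated recurrent units, trained with Lion or AdamW. Arrays are numpy
float64 throughout; graphs are built dynamically and freed after ``backward``.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "stack",
    "Module",
    "Linear",
    "LayerNorm",
    "MLP",
    "MultiheadAttention",
    "GRU",
    "Lion",
    "AdamW",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference fast path)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ------------------------------------------------------

    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * sig)

        return Tensor._make(out_data, (self,), backward)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g):
            self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shape ops ------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, a, b):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff ---------------------------------------------------------

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor without grad")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                if p.requires_grad:
                    visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
        # free the graph
        for t in topo:
            if t is not self:
                t._parents = ()
                t._backward = None


def concat(tensors, axis=0):
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    """Base class: children discovered by attribute inspection."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in, n_out, rng, zero_init=False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class MLP(Module):
    """Feed-forward stack with SiLU activations on hidden layers."""

    def __init__(self, dims, rng, zero_init_last=False):
        self.layers = [
            Linear(a, b, rng, zero_init=(zero_init_last and i == len(dims) - 2))
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x


class MultiheadAttention(Module):
    """Self-attention over the token axis of a (batch, tokens, embed) tensor."""

    def __init__(self, embed_dim, n_heads, rng):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.wq = Linear(embed_dim, embed_dim, rng)
        self.wk = Linear(embed_dim, embed_dim, rng)
        self.wv = Linear(embed_dim, embed_dim, rng)
        self.wo = Linear(embed_dim, embed_dim, rng)

    def __call__(self, x):
        b, t, e = x.shape
        h, d = self.n_heads, self.head_dim

        def split(y):  # (b, t, e) -> (b, h, t, d)
            return y.reshape(b, t, h, d).swapaxes(1, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d))
        att = scores.softmax(axis=-1)
        out = (att @ v).swapaxes(1, 2).reshape(b, t, e)
        return self.wo(out)


class GRUCell(Module):
    def __init__(self, n_in, n_hidden, rng):
        s = math.sqrt(1.0 / n_hidden)
        def mat(a, b):
            return Tensor(rng.uniform(-s, s, size=(a, b)), requires_grad=True)

        self.wxz, self.whz = mat(n_in, n_hidden), mat(n_hidden, n_hidden)
        self.wxr, self.whr = mat(n_in, n_hidden), mat(n_hidden, n_hidden)
        self.wxn, self.whn = mat(n_in, n_hidden), mat(n_hidden, n_hidden)
        self.bz = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.br = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.bn = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.bhn = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.n_hidden = n_hidden

    def __call__(self, x, h):
        z = (x @ self.wxz + h @ self.whz + self.bz).sigmoid()
        r = (x @ self.wxr + h @ self.whr + self.br).sigmoid()
        n = (x @ self.wxn + r * (h @ self.whn + self.bhn) + self.bn).tanh()
        return (1.0 - z) * n + z * h


class GRU(Module):
    """Stacked GRU; returns the final-step hidden state of the last layer."""

    def __init__(self, n_in, n_hidden, n_layers, rng):
        self.cells = [
            GRUCell(n_in if i == 0 else n_hidden, n_hidden, rng)
            for i in range(n_layers)
        ]
        self.n_hidden = n_hidden

    def __call__(self, x):
        # x: (batch, time, features)
        b, t, _ = x.shape
        steps = [x[:, j, :] for j in range(t)]
        for cell in self.cells:
            h = Tensor(np.zeros((b, cell.n_hidden)))
            outs = []
            for step in steps:
                h = cell(step, h)
                outs.append(h)
            steps = outs
        return steps[-1]


def apply_dropout(x, rate, rng, training):
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class Lion:
    """Sign-of-interpolated-momentum optimizer with decoupled weight decay."""

    def __init__(self, params, lr=5e-5, weight_decay=0.1, beta1=0.9, beta2=0.99):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = beta1, beta2
        self.m = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, m in zip(self.params, self.m):
            if p.grad is None:
                continue
            update = np.sign(self.b1 * m + (1.0 - self.b1) * p.grad)
            p.data -= self.lr * (update + self.wd * p.data)
            m *= self.b2
            m += (1.0 - self.b2) * p.grad


class AdamW:
    def __init__(self, params, lr=1e-3, weight_decay=0.1, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
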