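"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core behind the convolutional patch encoder,
the transformer aggregators and the gene-set autoencoder.  It implements a
small define-by-run tape: each operation returns a :class:`Tensor` that
remembers its parents and a closure computing vector-Jacobian products.
Only the operations the package actually needs exist here — dense and
depthwise 2-D convolution, batch/layer normalisation, softmax, matmul and
elementwise arithmetic — all in float32, all deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------

class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` leaf."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(-self, _wrap(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return mul(self, reciprocal(_wrap(other)))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  _parents=tuple(parents) if req else (),
                  _backward=backward if req else None)


# ---------------------------------------------------------------------------
# Elementwise and reduction primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def bwd(g):
        a._accum(g * s)

    return _node(a.data * s, (a,), bwd)


def reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.data

    def bwd(g):
        a._accum(-g * inv * inv)

    return _node(inv, (a,), bwd)


def texp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def bwd(g):
        a._accum(g * e)

    return _node(e, (a,), bwd)


def tlog(a: Tensor) -> Tensor:
    def bwd(g):
        a._accum(g / a.data)

    return _node(np.log(a.data), (a,), bwd)


def tsqrt(a: Tensor) -> Tensor:
    r = np.sqrt(a.data)

    def bwd(g):
        a._accum(g * 0.5 / r)

    return _node(r, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g):
        a._accum(g * mask)

    return _node(a.data * mask, (a,), bwd)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def bwd(g):
        a._accum(g * (1.0 - t * t))

    return _node(t, (a,), bwd)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                gg = np.expand_dims(gg, ax)
        a._accum(np.broadcast_to(gg, a.data.shape).astype(DTYPE))

    return _node(out_data, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul_scalar(tsum(a, axis, keepdims), 1.0 / float(n))


def square(a: Tensor) -> Tensor:
    def bwd(g):
        a._accum(g * 2.0 * a.data)

    return _node(a.data * a.data, (a,), bwd)


# ---------------------------------------------------------------------------
# Shape primitives
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape

    def bwd(g):
        a._accum(g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), bwd)


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.data.ndim)))
    inv = np.argsort(axes)

    def bwd(g):
        a._accum(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), bwd)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accum(g[tuple(sl)])

    return _node(np.concatenate([p.data for p in parts], axis=axis), parts, bwd)


def getitem(a: Tensor, idx) -> Tensor:
    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _node(a.data[idx], (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad or a._parents:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._parents:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bwd)


# ---------------------------------------------------------------------------
# Fused neural primitives
# ---------------------------------------------------------------------------

def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum(y * (g - dot))

    return _node(y, (a,), bwd)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * weight.data + bias.data
    n = x.data.shape[-1]

    def bwd(g):
        if weight.requires_grad:
            weight._accum((g * xhat).reshape(-1, n).sum(axis=0))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, n).sum(axis=0))
        gx = g * weight.data
        gxhat_sum = gx.sum(axis=-1, keepdims=True)
        gxhat_dot = (gx * xhat).sum(axis=-1, keepdims=True)
        x._accum(inv * (gx - gxhat_sum / n - xhat * gxhat_dot / n))

    return _node(out_data, (x, weight, bias), bwd)


def batch_norm_2d(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Channel-wise normalisation over (batch, H, W) using batch statistics.

    Statistics come from the current batch in both training and inference:
    a bag of patches is always processed as one batch, so the output is a
    deterministic function of the bag.
    """
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    w = weight.data.reshape(1, -1, 1, 1)
    b = bias.data.reshape(1, -1, 1, 1)
    out_data = xhat * w + b

    def bwd(g):
        if weight.requires_grad:
            weight._accum((g * xhat).sum(axis=axes))
        if bias.requires_grad:
            bias._accum(g.sum(axis=axes))
        gx = g * w
        s1 = gx.sum(axis=axes, keepdims=True)
        s2 = (gx * xhat).sum(axis=axes, keepdims=True)
        x._accum(inv * (gx - s1 / m - xhat * s2 / m))

    return _node(out_data, (x, weight, bias), bwd)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0,
           depthwise: bool = False) -> Tensor:
    """2-D convolution; ``depthwise=True`` applies one kernel per channel.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw) or (C, 1, kh, kw) depthwise.
    """
    n, cin, h, wd = x.data.shape
    kh, kw = w.data.shape[2], w.data.shape[3]
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("input smaller than kernel")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride, ho, wo)
    if depthwise:
        out_data = np.einsum("ncijhw,cij->nchw", cols, w.data[:, 0], optimize=True)
    else:
        c2 = cols.reshape(n, cin * kh * kw, ho * wo)
        w2 = w.data.reshape(w.data.shape[0], cin * kh * kw)
        out_data = (w2 @ c2).reshape(n, w.data.shape[0], ho, wo)

    def bwd(g):
        if w.requires_grad:
            if depthwise:
                gw = np.einsum("nchw,ncijhw->cij", g, cols, optimize=True)
                w._accum(gw[:, None])
            else:
                g2 = g.reshape(n, -1, ho * wo)
                c2b = cols.reshape(n, cin * kh * kw, ho * wo)
                gw = np.einsum("nop,ncp->oc", g2, c2b, optimize=True)
                w._accum(gw.reshape(w.data.shape))
        if x.requires_grad or x._parents:
            gxp = np.zeros(xp.shape, dtype=DTYPE)
            if depthwise:
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                            g * w.data[:, 0, i, j][None, :, None, None]
            else:
                g2 = g.reshape(n, -1, ho * wo)
                for i in range(kh):
                    for j in range(kw):
                        contrib = np.einsum("nop,oc->ncp", g2, w.data[:, :, i, j],
                                            optimize=True).reshape(n, cin, ho, wo)
                        gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += contrib
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return _node(out_data, (x, w), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    h, w = x.data.shape[2], x.data.shape[3]
    out_data = x.data.mean(axis=(2, 3))

    def bwd(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).astype(DTYPE))

    return _node(out_data, (x,), bwd)


def cross_entropy_logits(logits: Tensor, target: int) -> Tensor:
    """Scalar cross-entropy of a (1, K) logits row against an integer label."""
    z = logits.data.reshape(-1)
    m = z.max()
    lse = m + math.log(np.exp(z - m).sum())
    p = np.exp(z - lse)

    def bwd(g):
        gz = p.copy()
        gz[target] -= 1.0
        logits._accum((g * gz).reshape(logits.data.shape))

    return _node(np.asarray(lse - z[target], dtype=DTYPE), (logits,), bwd)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Lightweight parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value) -> Iterable[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


class Linear(Module):
    """Dense layer with uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) init.

    The cooler uniform init (rather than the ReLU-gain normal used for the
    convolutions) keeps attention logits in a trainable range at start.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = 1.0 / math.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)).astype(DTYPE),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, depthwise: bool = False):
        cin_eff = 1 if depthwise else cin
        self.weight = Tensor(_kaiming(rng, (cout, cin_eff, k, k), cin_eff * k * k),
                             requires_grad=True)
        self.stride, self.padding, self.depthwise = stride, padding, depthwise

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.stride, self.padding, self.depthwise)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        self.weight = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm_2d(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.weight = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias)


class Adam:
    """Adam optimizer (Kingma & Ba) over an explicit parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled decay
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
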