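"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float32 ndarray and
records, for every produced value, a closure that maps the output gradient
back onto the operands. ``backward()`` runs these closures in reverse
topological order. Only the operations needed by the fusion-IQA networks are
provided (dense/conv algebra, pooling, normalization, pointwise
nonlinearities, reductions).

All convolutional inputs use NCHW layout.
"""

from __future__ import annotations

import contextlib

import numpy as np

_FLOAT = np.float32

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_FLOAT)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---------------------------------------------------------------- infra
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs here can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=_FLOAT)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free graph references
                node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_FLOAT, copy=True)
        else:
            self.grad += grad

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            a._accum(g * sign)

        return Tensor._make(np.abs(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        e = np.exp(-np.abs(a.data))  # overflow-safe in both tails
        s = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(_FLOAT)

        def backward(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), backward)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = np.where(a.data > 0, _FLOAT(1.0), _FLOAT(slope))

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def relu(self):
        return self.leaky_relu(0.0)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        """Clip values; gradient is passed only where the value was interior."""
        a = self
        clipped = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask *= a.data > lo
        if hi is not None:
            mask *= a.data < hi

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(clipped, (a,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).astype(_FLOAT))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).astype(_FLOAT))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Max over `axis`; gradient routed to (one) argmax element."""
        a = self
        idx = a.data.argmax(axis=axis, keepdims=True)
        out = np.take_along_axis(a.data, idx, axis=axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            buf = np.zeros_like(a.data)
            np.put_along_axis(buf, idx, gg, axis=axis)
            a._accum(buf)

        return Tensor._make(out if keepdims else out.squeeze(axis), (a,), backward)

    def min(self, axis, keepdims: bool = False):
        return -((-self).max(axis, keepdims))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            buf = np.zeros_like(a.data)
            buf[idx] = g
            a._accum(buf)

        return Tensor._make(a.data[idx], (a,), backward)

    # ---------------------------------------------------------------- shape
    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def backward(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis`, splitting the gradient back to each operand."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
    a = x
    d = a.data
    out = np.maximum(d, 0) + np.log1p(np.exp(-np.abs(d)))
    sig = 1.0 / (1.0 + np.exp(-d))

    def backward(g):
        a._accum(g * sig)

    return Tensor._make(out, (a,), backward)


# ------------------------------------------------------------------ conv ops
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Patch matrix in NCHW-native order: (N, C*kh*kw, Ho*Wo).

    Built from kh*kw strided slice copies (no transposed gather), so the
    subsequent matmuls run on contiguous blocks.
    """
    n, c, h, w = x.shape
    hp, wp = h + 2 * pad, w + 2 * pad
    if pad:
        xp = np.zeros((n, c, hp, wp), dtype=_FLOAT)
        xp[:, :, pad : pad + h, pad : pad + w] = x
        x = xp
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=_FLOAT)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride,
                                 j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo, hp, wp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    n, c, h, wd = x.data.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    cols, ho, wo, hp, wp = _im2col(x.data, kh, kw, stride, pad)
    wflat = w.data.reshape(o, -1)
    out = wflat @ cols  # (O, CKK) @ (N, CKK, L) -> (N, O, L)
    if b is not None:
        out += b.data[None, :, None]
    out = out.reshape(n, o, ho, wo)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(n, o, ho * wo)
        if w.requires_grad:
            dw = (gmat @ cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (wflat.T @ gmat).reshape(n, c, kh, kw, ho, wo)
            dxp = np.zeros((n, c, hp, wp), dtype=_FLOAT)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride,
                        j : j + stride * wo : stride] += dcols[:, :, i, j]
            x._accum(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    return Tensor._make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial size ({h},{w}) not divisible by {k}")
    v = x.data.reshape(n, c, h // k, k, w // k, k)
    out = v.mean(axis=(3, 5))

    def backward(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gg)

    return Tensor._make(out, (x,), backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial size ({h},{w}) not divisible by {k}")
    v = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, h // k, w // k, k * k)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dv = np.zeros((n, c, h // k, w // k, k * k), dtype=_FLOAT)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dv = dv.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dv.reshape(n, c, h, w))

    return Tensor._make(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def backward(g):
        gg = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor._make(out, (x,), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    Updates `running_mean`/`running_var` in place when training.
    """
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = n * h * w

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                a = gs.sum(axis=(0, 2, 3)) / m
                bxh = (gs * xhat).sum(axis=(0, 2, 3)) / m
                dx = (gs - a[None, :, None, None]
                      - xhat * bxh[None, :, None, None]) / std[None, :, None, None]
            else:
                dx = gs / std[None, :, None, None]
            x._accum(dx.astype(_FLOAT))

    return Tensor._make(out, (x, gamma, beta), backward)
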