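"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the generator/discriminator networks and
their losses need: elementwise arithmetic, matmul, 2-D convolution,
nearest/bilinear resampling, reductions and concatenation.  Gradients are
accumulated on a dynamically built tape and released after ``backward``.

All tensors are float64; network sizes here are small enough that the extra
precision is cheaper than chasing float32 accumulation artifacts in tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "absolute",
    "mean",
    "tsum",
    "reshape",
    "concat",
    "matmul",
    "conv2d",
    "upsample_nearest2d",
    "resize_bilinear",
]


class Tensor:
    """A node in the autodiff graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- graph plumbing ------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # free the tape so intermediate buffers can be collected
        for t in topo:
            t._backward = None
            t._prev = ()

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise nonlinearities ---------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))

    def bwd(g):
        x._accumulate(g * (x.data > 0))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _prev=(x,))

    def bwd(g):
        x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, _prev=(x,))
    out._backward = lambda g: x._accumulate(g * e)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _prev=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)
    out = Tensor(r, _prev=(x,))
    out._backward = lambda g: x._accumulate(g * 0.5 / r)
    return out


def absolute(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), _prev=(x,))
    out._backward = lambda g: x._accumulate(g * np.sign(x.data))
    return out


# -- reductions and reshaping ------------------------------------------


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(x.data.mean(axis=axis, keepdims=keepdims), _prev=(x,))
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in np.atleast_1d(axis)]
    )

    def bwd(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        x._accumulate(np.broadcast_to(g, x.data.shape) / n)

    out._backward = bwd
    return out


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), _prev=(x,))

    def bwd(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    out._backward = bwd
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), _prev=(x,))
    out._backward = lambda g: x._accumulate(g.reshape(x.data.shape))
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out


def matmul(x: Tensor, w: Tensor) -> Tensor:
    out = Tensor(x.data @ w.data, _prev=(x, w))

    def bwd(g):
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)

    out._backward = bwd
    return out


# -- spatial operations (NCHW) -----------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, kernel (O, C, kh, kw)."""
    n, c, h, ww = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (ww + 2 * padding - kw) // stride + 1
    y = np.zeros((n, o, ho, wo))
    # small kernels: accumulate one tap at a time with a big matmul each
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            y += np.einsum("nchw,oc->nohw", patch, w.data[:, :, i, j], optimize=True)
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _prev=prev)

    def bwd(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i, i + stride * ho, stride),
                      slice(j, j + stride * wo, stride))
                gw[:, :, i, j] = np.einsum("nchw,nohw->oc", xp[sl], g, optimize=True)
                gxp[sl] += np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
        if padding:
            gx = gxp[:, :, padding:-padding, padding:-padding]
        else:
            gx = gxp
        x._accumulate(gx)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    y = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(y, _prev=(x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        g = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(g)

    out._backward = bwd
    return out


def _linear_coeffs(n_in: int, n_out: int):
    """Separable bilinear resampling coefficients (align_corners=False)."""
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = pos - i0
    return i0, i1, f


def resize_bilinear(x: Tensor, out_hw) -> Tensor:
    """Bilinear grid resampling of an NCHW tensor to ``out_hw``."""
    ho, wo = out_hw
    n, c, h, w = x.data.shape
    if (h, w) == (ho, wo):
        return x
    r0, r1, fr = _linear_coeffs(h, ho)
    c0, c1, fc = _linear_coeffs(w, wo)
    top = x.data[:, :, r0, :] * (1 - fr)[None, None, :, None] + \
        x.data[:, :, r1, :] * fr[None, None, :, None]
    y = top[:, :, :, c0] * (1 - fc) + top[:, :, :, c1] * fc
    out = Tensor(y, _prev=(x,))

    def bwd(g):
        gtop = np.zeros((n, c, ho, w))
        np.add.at(gtop, (slice(None), slice(None), slice(None), c0), g * (1 - fc))
        np.add.at(gtop, (slice(None), slice(None), slice(None), c1), g * fc)
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)),
                  gtop * (1 - fr)[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)),
                  gtop * fr[None, None, :, None])
        x._accumulate(gx)

    out._backward = bwd
    return out
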