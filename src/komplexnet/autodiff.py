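"""Reverse-mode automatic differentiation on numpy arrays.

The network unrolls a recurrent phase dynamic over many timesteps and trains
the coupling kernels by backpropagation through time, so every operation used
in the forward pass needs a gradient.  This module provides a small tensor
engine (a :class:`Tensor` wrapping an ``ndarray`` plus a backward closure) and
a functional namespace (``sin``, ``conv2d``, ...) that dispatches on the input
type: plain ``ndarray`` inputs are computed eagerly with numpy, ``Tensor``
inputs record the graph.  Shared math code in the rest of the package is
written once against this namespace and serves both inference and training.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "as_data",
    "sin",
    "cos",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "absolute",
    "relu",
    "sigmoid",
    "arctan2",
    "summation",
    "mean",
    "matmul",
    "reshape",
    "conv2d",
    "dilate2d",
    "wrap_angle",
    "Adam",
]


def as_data(x):
    """Return the underlying ndarray of ``x`` (identity for plain arrays)."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with a gradient and the closure to propagate it."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    # keep numpy from broadcasting a Tensor elementwise as an object scalar:
    # defer every ndarray <op> Tensor to the reflected Tensor method instead
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    # -- graph bookkeeping -------------------------------------------------
    def _accumulate(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not isinstance(t, Tensor):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                # interior nodes never expose their grad; freeing it caps the
                # memory of long unrolled graphs
                t.grad = None
                t._backward = None
                t._parents = ()

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = _ensure_like(other, self.data)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor(self.data + o.data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_ensure_like(other, self.data))

    def __rsub__(self, other):
        return _ensure_like(other, self.data) + (-self)

    def __mul__(self, other):
        o = _ensure_like(other, self.data)

        def bwd(g):
            self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor(self.data * o.data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _ensure_like(other, self.data)

        def bwd(g):
            self._accumulate(_unbroadcast(g / o.data, self.data.shape))
            o._accumulate(_unbroadcast(-g * self.data / o.data**2, o.data.shape))

        return Tensor(self.data / o.data, (self, o), bwd)

    def __rtruediv__(self, other):
        return _ensure_like(other, self.data) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data, dtype=float)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.data[idx], (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        return summation(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, *shape)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x), requires_grad=False)


def _ensure_like(x, ref: np.ndarray) -> Tensor:
    """Wrap a constant, keeping python scalars in the reference dtype so a
    float literal does not silently upcast a float32 graph to float64."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if arr.dtype == np.float64 and ref.dtype == np.float32:
        arr = arr.astype(np.float32)
    return Tensor(arr, requires_grad=False)


# -- elementwise functions -------------------------------------------------

def _unary(x, fwd, dfun):
    if not isinstance(x, Tensor):
        return fwd(np.asarray(x))
    y = fwd(x.data)

    def bwd(g):
        x._accumulate(g * dfun(x.data, y))

    return Tensor(y, (x,), bwd)


def sin(x):
    return _unary(x, np.sin, lambda d, y: np.cos(d))


def cos(x):
    return _unary(x, np.cos, lambda d, y: -np.sin(d))


def tanh(x):
    return _unary(x, np.tanh, lambda d, y: 1.0 - y**2)


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, y: 0.5 / np.maximum(y, 1e-300))


def absolute(x):
    return _unary(x, np.abs, lambda d, y: np.sign(d))


def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, y: (d > 0).astype(float))


def sigmoid(x):
    def fwd(d):
        out = np.empty_like(d, dtype=float)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _unary(x, fwd, lambda d, y: y * (1.0 - y))


def arctan2(y, x):
    """Four-quadrant arctangent; gradient is zeroed at the origin, where the
    angle is conventionally 0 and the caller's amplitude vanishes anyway."""
    if not isinstance(y, Tensor) and not isinstance(x, Tensor):
        return np.arctan2(np.asarray(y), np.asarray(x))
    yt, xt = _ensure(y), _ensure(x)
    r2 = yt.data**2 + xt.data**2
    safe = np.where(r2 == 0.0, 1.0, r2)
    out = np.arctan2(yt.data, xt.data)

    def bwd(g):
        live = (r2 > 0).astype(float)
        yt._accumulate(_unbroadcast(g * live * xt.data / safe, yt.data.shape))
        xt._accumulate(_unbroadcast(-g * live * yt.data / safe, xt.data.shape))

    return Tensor(out, (yt, xt), bwd)


# -- reductions and shaping ------------------------------------------------

def summation(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)
    y = x.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return Tensor(y, (x,), bwd)


def mean(x, axis=None, keepdims=False):
    data = as_data(x)
    if axis is None:
        n = data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = math.prod(data.shape[a] for a in axes)
    return summation(x, axis=axis, keepdims=keepdims) / n


def reshape(x, *shape):
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    if not isinstance(x, Tensor):
        return np.reshape(x, shape)
    old = x.data.shape

    def bwd(g):
        x._accumulate(g.reshape(old))

    return Tensor(x.data.reshape(shape), (x,), bwd)


def matmul(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.asarray(a) @ np.asarray(b)
    at, bt = _ensure(a), _ensure(b)
    if at.data.ndim != 2 or bt.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def bwd(g):
        at._accumulate(g @ bt.data.T)
        bt._accumulate(at.data.T @ g)

    return Tensor(at.data @ bt.data, (at, bt), bwd)


# -- convolution -----------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    # xp: (N, C, Hp, Wp) already padded
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)


def _pad_pair(padding):
    return padding if isinstance(padding, tuple) else (padding, padding)


def _conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding):
    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    ph, pw = _pad_pair(padding)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw, stride)  # (N, C, Ho, Wo, kh, kw)
    n_, _, ho, wo, _, _ = cols.shape
    mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out = mat @ w.reshape(co, -1).T
    return out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2), mat, (ho, wo)


def _fft_size(h, kh, wd, kw):
    from scipy.fft import next_fast_len

    return (next_fast_len(h + kh - 1, real=True), next_fast_len(wd + kw - 1, real=True))


def _conv2d_fft(x, w, padding):
    """Stride-1 cross-correlation via FFT; returns (out, cache for bwd).

    The kernel taps of the first-layer coupling kernels cover large
    neighborhoods on full-resolution grids, where im2col is memory-bound;
    one batched FFT per field is much cheaper there.
    """
    from scipy import fft as sfft

    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    ph, pw = _pad_pair(padding)
    ho, wo = h + 2 * ph - kh + 1, wd + 2 * pw - kw + 1
    size = _fft_size(h, kh, wd, kw)
    xf = sfft.rfft2(x, s=size)                      # (N, C, Fh, Fw)
    wf_flip = sfft.rfft2(np.ascontiguousarray(w[:, :, ::-1, ::-1]), s=size)
    prod = np.einsum("ncf,ocf->nof", xf.reshape(n, c, -1),
                     wf_flip.reshape(co, ci, -1)).reshape(n, co, *xf.shape[2:])
    full = sfft.irfft2(prod, s=size)
    out = full[:, :, kh - 1 - ph : kh - 1 - ph + ho, kw - 1 - pw : kw - 1 - pw + wo]
    return np.ascontiguousarray(out, dtype=x.dtype), (xf, size)


def _conv2d_fft_backward(g, x, w, xf, size, padding):
    from scipy import fft as sfft

    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    ph, pw = _pad_pair(padding)
    g = np.ascontiguousarray(g, dtype=x.dtype)
    gf = sfft.rfft2(g, s=size)                      # (N, Co, Fh, Fw)
    wf = sfft.rfft2(w, s=size)                      # (Co, Ci, Fh, Fw)
    # dx[t] = sum_i g[i] w[t + p - i]  ->  crop of conv_full(g, w) at offset p
    prod_x = np.einsum("nof,ocf->ncf", gf.reshape(n, co, -1),
                       wf.reshape(co, ci, -1)).reshape(n, c, *gf.shape[2:])
    dx = sfft.irfft2(prod_x, s=size)[:, :, ph : ph + h, pw : pw + wd]
    # dW[u] = sum_t x[t] g[t + p - u]  ->  crop of conv_full(x, flip(g))
    gf_flip = sfft.rfft2(np.ascontiguousarray(g[:, :, ::-1, ::-1]), s=size)
    prod_w = np.einsum("ncf,nof->ocf", xf.reshape(n, c, -1),
                       gf_flip.reshape(n, co, -1)).reshape(co, ci, *xf.shape[2:])
    ho = h + 2 * ph - kh + 1
    wo = wd + 2 * pw - kw + 1
    full_w = sfft.irfft2(prod_w, s=size)
    dw = full_w[:, :, ho - 1 - ph : ho - 1 - ph + kh, wo - 1 - pw : wo - 1 - pw + kw]
    return dx.astype(x.dtype), np.ascontiguousarray(dw, dtype=w.dtype)


def _use_fft(x, w, stride):
    kh, kw = w.shape[2:]
    return stride == 1 and kh * kw >= 25 and x.shape[2] * x.shape[3] >= 256


def conv2d(x, w, stride: int = 1, padding=0):
    """Bias-free 2-D cross-correlation, NCHW layout, zero padding.

    ``out[n, o, i, j] = sum_{c,u,v} w[o, c, u, v] * x[n, c, i*s+u-p, j*s+v-p]``
    ``padding`` is an int or an ``(ph, pw)`` pair.  Large stride-1 kernels go
    through an FFT path; strided or small convolutions through im2col.
    """
    if not isinstance(x, Tensor) and not isinstance(w, Tensor):
        x, w = np.asarray(x), np.asarray(w)
        if _use_fft(x, w, stride):
            return _conv2d_fft(x, w, padding)[0]
        out, _, _ = _conv2d_forward(x, w, stride, padding)
        return out
    if _use_fft(as_data(x), as_data(w), stride):
        xt, wt = _ensure(x), _ensure(w)
        out, (xf, size) = _conv2d_fft(xt.data, wt.data, padding)

        def bwd_fft(g):
            dx, dw = _conv2d_fft_backward(g, xt.data, wt.data, xf, size, padding)
            xt._accumulate(dx)
            wt._accumulate(dw)

        return Tensor(out, (xt, wt), bwd_fft)
    xt, wt = _ensure(x), _ensure(w)
    xd = xt.data
    wd = wt.data
    out, mat, (ho, wo) = _conv2d_forward(xd, wd, stride, padding)
    del mat  # rebuilt on demand in bwd: keeping it alive across an unrolled
    # recurrence would hold one im2col matrix per timestep in memory
    n, c, h, wdt = xd.shape
    co, ci, kh, kw = wd.shape
    ph, pw = _pad_pair(padding)

    def bwd(g):
        # g: (N, Co, Ho, Wo)
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = _im2col(xp, kh, kw, stride)
        mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        wt._accumulate((gmat.T @ mat).reshape(co, ci, kh, kw))
        del cols, mat
        dcols = (gmat @ wd.reshape(co, -1)).reshape(n, ho, wo, c, kh, kw)
        hp, wp = h + 2 * ph, wdt + 2 * pw
        dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
        for u in range(kh):
            for v in range(kw):
                dxp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += dcols[
                    :, :, :, :, u, v
                ].transpose(0, 3, 1, 2)
        dxp = dxp[:, :, ph : hp - ph if ph else hp, pw : wp - pw if pw else wp]
        xt._accumulate(dxp)

    return Tensor(out, (xt, wt), bwd)


def dilate2d(x, stride: int, out_hw: tuple):
    """Zero-stuff the two trailing spatial axes: ``y[..., i*s, j*s] = x[..., i, j]``.

    Used to lift a strided layer's grid back onto the full-resolution grid
    before a transposed-orientation convolution (top-down feedback path).
    """
    oh, ow = out_hw
    if not isinstance(x, Tensor):
        x = np.asarray(x)
        y = np.zeros(x.shape[:-2] + (oh, ow), dtype=x.dtype)
        y[..., :: stride, :: stride][..., : x.shape[-2], : x.shape[-1]] = x
        return y
    xd = x.data
    y = np.zeros(xd.shape[:-2] + (oh, ow), dtype=xd.dtype)
    y[..., ::stride, ::stride][..., : xd.shape[-2], : xd.shape[-1]] = xd

    def bwd(g):
        x._accumulate(
            g[..., ::stride, ::stride][..., : xd.shape[-2], : xd.shape[-1]].copy()
        )

    return Tensor(y, (x,), bwd)


def wrap_angle(x):
    """Wrap to the half-open interval (-pi, pi].

    The wrap offset is an integer multiple of 2*pi and piecewise constant, so
    the gradient passes through unchanged.
    """
    data = as_data(x)
    offset = (-2.0 * np.pi * np.ceil((data - np.pi) / (2.0 * np.pi))).astype(data.dtype)
    if isinstance(x, Tensor):
        return x + offset
    return data + offset


# -- optimizer -------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=float) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=float) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
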