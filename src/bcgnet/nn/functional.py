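"""Differentiable operations for 1D convolutional networks.

Conventions: feature maps are ``(batch, channels, length)``; dense inputs
are ``(batch, features)``.  Convolutions are cross-correlations (the deep
learning convention).  Max pooling uses ceil mode so short inputs never
collapse to length zero; adaptive average pooling follows the standard
``floor(i*L/out) .. ceil((i+1)*L/out)`` binning.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf, expit

from .autograd import Tensor, make_op

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse a NumPy broadcast)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return make_op(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape),
                                           _unbroadcast(g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return make_op(out, (a, b), lambda g: (_unbroadcast(g * b.data, a.data.shape),
                                           _unbroadcast(g * a.data, b.data.shape)))


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-form) Gaussian error linear unit."""
    xd = x.data
    phi = 0.5 * (1.0 + erf(xd * _INV_SQRT2))
    out = xd * phi

    def bw(g):
        dphi = phi + xd * np.exp(-0.5 * xd * xd) * _INV_SQRT2PI
        return (g * dphi,)

    return make_op(out, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)
    return make_op(s, (x,), lambda g: (g * s * (1.0 - s),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return make_op(x.data * mask, (x,), lambda g: (g * mask,))


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    return make_op(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return make_op(out, tuple(tensors), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Dense layer: ``x @ w.T + b`` with ``w`` shaped (out, in)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def bw(g):
        gx = g @ w.data
        gw = g.T @ x.data
        gb = g.sum(axis=0) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    inputs = (x, w, b) if b is not None else (x, w)
    return make_op(out, inputs, bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """1D cross-correlation.  ``x``: (N,Cin,L); ``w``: (Cout,Cin,K)."""
    n, cin, length = x.data.shape
    cout, cin_w, k = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv1d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    lp = xp.shape[2]
    if lp < k:
        raise ValueError(f"conv1d: padded length {lp} shorter than kernel {k}")
    lout = (lp - k) // stride + 1
    windows = sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]  # (N,Cin,Lout,K)
    out = np.einsum("nclk,ock->nol", windows, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]

    def bw(g):
        gw = np.einsum("nclk,nol->ock", windows, g, optimize=True)
        gxp = np.zeros_like(xp)
        # scatter-add per kernel offset
        for kk in range(k):
            # output position j reads xp[:, :, j*stride + kk]
            contrib = np.einsum("nol,oc->ncl", g, w.data[:, :, kk], optimize=True)
            gxp[:, :, kk:kk + stride * lout:stride] += contrib
        gx = gxp[:, :, padding:lp - padding] if padding else gxp
        gb = g.sum(axis=(0, 2)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    inputs = (x, w, b) if b is not None else (x, w)
    return make_op(out, inputs, bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,C,L) or (N,C); stats per channel.

    Running statistics are updated in place during training (they are
    plain arrays owned by the calling module, not graph nodes).
    """
    xd = x.data
    axes = (0, 2) if xd.ndim == 3 else (0,)
    shape = (1, -1, 1) if xd.ndim == 3 else (1, -1)
    if training:
        mean = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        m = xd.size // xd.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        # unbiased variance for the running estimate, as is conventional
        running_var *= 1.0 - momentum
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bw(g):
        ggamma = (g * xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        gs = gamma.data.reshape(shape) * inv_std.reshape(shape)
        if training:
            m = xd.size // xd.shape[1]
            gmean = g.mean(axis=axes).reshape(shape)
            gdot = (g * xhat).mean(axis=axes).reshape(shape)
            gx = gs * (g - gmean - xhat * gdot)
        else:
            gx = gs * g
        return (gx, ggamma, gbeta)

    return make_op(out, (x, gamma, beta), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return make_op(x.data * mask, (x,), lambda g: (g * mask,))


def max_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Max pooling with ceil mode (trailing partial window kept)."""
    n, c, length = x.data.shape
    lout = -(-max(length - kernel, 0) // stride) + 1 if length >= 1 else 0
    pad_to = (lout - 1) * stride + kernel
    xp = x.data
    if pad_to > length:
        xp = np.pad(x.data, ((0, 0), (0, 0), (0, pad_to - length)),
                    constant_values=-np.inf)
    windows = sliding_window_view(xp, kernel, axis=2)[:, :, ::stride, :]
    arg = windows.argmax(axis=3)  # (N,C,Lout)
    out = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]

    def bw(g):
        gx = np.zeros((n, c, pad_to), dtype=g.dtype)
        pos = np.arange(lout) * stride + arg  # absolute source index
        np.add.at(gx, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], pos), g)
        return (gx[:, :, :length],)

    return make_op(out, (x,), bw)


def _adaptive_bins(length: int, out: int):
    starts = (np.arange(out) * length) // out
    ends = -(-(np.arange(1, out + 1) * length) // out)
    return starts, ends


def adaptive_avg_pool1d(x: Tensor, out_length: int) -> Tensor:
    n, c, length = x.data.shape
    starts, ends = _adaptive_bins(length, out_length)
    out = np.empty((n, c, out_length), dtype=x.data.dtype)
    for i in range(out_length):
        out[:, :, i] = x.data[:, :, starts[i]:ends[i]].mean(axis=2)

    def bw(g):
        gx = np.zeros((n, c, length), dtype=g.dtype)
        for i in range(out_length):
            gx[:, :, starts[i]:ends[i]] += (g[:, :, i] / (ends[i] - starts[i]))[..., None]
        return (gx,)

    return make_op(out, (x,), bw)


def interp_matrix(length_in: int, length_out: int, dtype=np.float64) -> np.ndarray:
    """Linear-interpolation matrix M with ``y = x @ M`` along the last axis.

    Endpoints map to endpoints (align-corners convention); a length-1
    source broadcasts to every output position.
    """
    m = np.zeros((length_in, length_out), dtype=dtype)
    if length_in == 1:
        m[0, :] = 1.0
        return m
    if length_out == 1:
        src = (length_in - 1) / 2.0
        lo = int(np.floor(src))
        frac = src - lo
        m[lo, 0] = 1.0 - frac
        if frac > 0:
            m[lo + 1, 0] = frac
        return m
    src = np.arange(length_out) * (length_in - 1) / (length_out - 1)
    lo = np.floor(src).astype(int)
    lo = np.minimum(lo, length_in - 2)
    frac = src - lo
    m[lo, np.arange(length_out)] += 1.0 - frac
    m[lo + 1, np.arange(length_out)] += frac
    return m


def interp_resize(x: Tensor, out_length: int) -> Tensor:
    """Resize (N,C,L) along the position axis by linear interpolation."""
    length = x.data.shape[2]
    mat = interp_matrix(length, out_length, dtype=x.data.dtype)
    out = np.einsum("ncl,lo->nco", x.data, mat, optimize=True)
    return make_op(out, (x,), lambda g: (np.einsum("nco,lo->ncl", g, mat, optimize=True),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return make_op(p, (x,), bw)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against raw logits."""
    ld = logits.data
    n = ld.shape[0]
    z = ld - ld.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return (g * p / n,)

    return make_op(np.asarray(loss), (logits,), bw)
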