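"""Differentiable operations on :class:`~mapseg.nn.core.Tensor`."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .core import Tensor, _make, _unbroadcast


def _wants(t: Tensor) -> bool:
    return t.requires_grad


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if _wants(a):
            a.accumulate(_unbroadcast(g, a.data.shape))
        if _wants(b):
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if _wants(a):
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if _wants(b):
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if _wants(a):
            a.accumulate(g * s)

    return _make(a.data * s, (a,), backward)


# ---------------------------------------------------------------- activations

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if _wants(a):
            a.accumulate(g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = expit(a.data)

    def backward(g):
        if _wants(a):
            a.accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


# ---------------------------------------------------------------- shape ops

def concat(tensors, axis=1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _wants(t):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        if _wants(a):
            full = np.zeros_like(a.data)
            full[idx] = g
            a.accumulate(full)

    return _make(a.data[idx].copy(), (a,), backward)


def swap_hw(a: Tensor) -> Tensor:
    """Transpose the two trailing spatial axes of a (B, C, H, W) tensor."""

    def backward(g):
        if _wants(a):
            a.accumulate(g.transpose(0, 1, 3, 2))

    return _make(np.ascontiguousarray(a.data.transpose(0, 1, 3, 2)), (a,), backward)


def mean(a: Tensor, axis, keepdims=True) -> Tensor:
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    n = 1
    for ax in axes:
        n *= a.data.shape[ax]
    out_data = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if _wants(a):
            if not keepdims:
                g = np.expand_dims(g, axes)
            a.accumulate(np.broadcast_to(g, a.data.shape) / n)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------- convolution

def _im2col(x, kh, kw, stride, pad):
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw
    )
    return cols, Ho, Wo


def _col2im(dcols, x_shape, kh, kw, stride, pad, Ho, Wo):
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + H, pad : pad + W]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias, stride=1, pad=0) -> Tensor:
    Cout, Cin, kh, kw = weight.data.shape
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(Cout, -1)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    B = x.data.shape[0]
    out_data = np.ascontiguousarray(out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2))
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Cout)
        if _wants(weight):
            weight.accumulate((gmat.T @ cols).reshape(weight.data.shape))
        if bias is not None and _wants(bias):
            bias.accumulate(gmat.sum(axis=0))
        if _wants(x):
            dcols = gmat @ wmat
            x.accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad, Ho, Wo))

    return _make(out_data, parents, backward)


def max_pool2d(x: Tensor, k=3, stride=2, pad=1) -> Tensor:
    """Forward-only max pooling (used inside the frozen encoder)."""
    if x.requires_grad or x._prev:
        raise NotImplementedError("max_pool2d is forward-only (frozen encoder)")
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf
    )
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return Tensor(win.max(axis=(4, 5)))


# ---------------------------------------------------------------- upsampling

_resize_cache: dict = {}


def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D bilinear interpolation matrix, half-pixel-centres convention."""
    key = (n_in, n_out)
    if key not in _resize_cache:
        A = np.zeros((n_out, n_in), dtype=np.float32)
        for i in range(n_out):
            src = (i + 0.5) * n_in / n_out - 0.5
            i0 = int(np.floor(src))
            f = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            A[i, i0c] += 1.0 - f
            A[i, i1c] += f
        _resize_cache[key] = A
    return _resize_cache[key]


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    B, C, H, W = x.data.shape
    Ah = bilinear_matrix(H, out_h)
    Aw = bilinear_matrix(W, out_w)
    out_data = np.matmul(np.matmul(Ah, x.data), Aw.T)

    def backward(g):
        if _wants(x):
            x.accumulate(np.matmul(np.matmul(Ah.T, g), Aw))

    return _make(out_data, (x,), backward)
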