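"""Convolution, resampling and pooling primitives.

Convolutions run as im2col + batched BLAS matmul, with a shift-accumulate
fast path for depthwise kernels.  Geometry (gather indices, col2im scatter
matrices, interpolation matrices) is cached per shape.  A module-level
profiler hook records multiply-accumulate counts when active.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse

from .tensor import Tensor, grad_enabled

# active ProfileReport (set by uwseg.profiling); conv/linear ops record into it
_PROFILER = None

_im2col_cache: dict = {}
_scatter_cache: dict = {}
_interp_cache: dict = {}


def _out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    eff = d * (k - 1) + 1
    return (n + 2 * p - eff) // s + 1


def _im2col_indices(h, w, kh, kw, s, p, d):
    key = (h, w, kh, kw, s, p, d)
    if key not in _im2col_cache:
        hp, wp = h + 2 * p, w + 2 * p
        ho, wo = _out_size(h, kh, s, p, d), _out_size(w, kw, s, p, d)
        oi = np.arange(ho) * s
        oj = np.arange(wo) * s
        ki = np.arange(kh) * d
        kj = np.arange(kw) * d
        pi = (oi[None, :] + ki[:, None])            # (kh, ho)
        pj = (oj[None, :] + kj[:, None])            # (kw, wo)
        # idx[k, l] with k = ki*kw+kj, l = oi*wo+oj
        idx = (pi[:, None, :, None] * wp + pj[None, :, None, :]).reshape(kh * kw, ho * wo)
        _im2col_cache[key] = (idx.astype(np.int64), hp, wp, ho, wo)
    return _im2col_cache[key]


def _scatter_matrix(h, w, kh, kw, s, p, d):
    key = (h, w, kh, kw, s, p, d)
    if key not in _scatter_cache:
        idx, hp, wp, ho, wo = _im2col_indices(h, w, kh, kw, s, p, d)
        kl = idx.size
        S = sparse.csr_matrix(
            (np.ones(kl, dtype=np.float32), (idx.ravel(), np.arange(kl))),
            shape=(hp * wp, kl),
        )
        _scatter_cache[key] = S
    return _scatter_cache[key]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, symmetric zero padding."""
    n, c, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if c // groups != cin_g or c % groups:
        raise ValueError(
            f"conv2d: input channels {c} incompatible with weight {weight.data.shape} "
            f"and groups {groups}")
    ho, wo = _out_size(h, kh, stride, padding, dilation), _out_size(w, kw, stride, padding, dilation)
    if _PROFILER is not None:
        macs = (cin_g * kh * kw + (1 if bias is not None else 0)) * cout * ho * wo * n
        _PROFILER.add(f"conv{kh}x{kw}", params_of(weight, bias), macs)

    if groups == cout and cin_g <= 4:
        return _dwconv2d(x, weight, bias, stride, padding, dilation, groups)

    idx, hp, wp, ho, wo = _im2col_indices(h, w, kh, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = xp.reshape(n, c, hp * wp)[:, :, idx]                   # (n, c, K, L)
    k = kh * kw
    cols_g = cols.reshape(n, groups, cin_g * k, ho * wo)          # (n, g, ck, L)
    wg = weight.data.reshape(groups, cout // groups, cin_g * k)   # (g, co, ck)
    out = np.matmul(wg, cols_g)                                   # (n, g, co, L)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)

    prev = (x, weight) + ((bias,) if bias is not None else ())
    needs = grad_enabled() and any(p.requires_grad for p in prev)
    res = Tensor(out, requires_grad=needs, _prev=prev if needs else ())
    if needs:
        def backward(g):
            gg = g.reshape(n, groups, cout // groups, ho * wo)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.matmul(gg, np.swapaxes(cols_g, -1, -2)).sum(axis=0)
                weight._accumulate(dw.reshape(weight.data.shape))
            if x.requires_grad:
                dcols = np.matmul(np.swapaxes(wg, -1, -2), gg)    # (n, g, ck, L)
                S = _scatter_matrix(h, w, kh, kw, stride, padding, dilation)
                flat = dcols.reshape(n * c, k * ho * wo)
                dxp = (S @ flat.T).T.reshape(n, c, hp, wp)
                if padding:
                    dxp = dxp[:, :, padding:padding + h, padding:padding + w]
                x._accumulate(np.ascontiguousarray(dxp))
        res._backward = backward
    return res


def _dwconv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
              stride: int, padding: int, dilation: int, groups: int) -> Tensor:
    """Grouped conv with one output channel per group (depthwise and friends)
    via shift-accumulate: memory-light, BLAS-free, vectorized over groups."""
    n, c, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    ho, wo = _out_size(h, kh, stride, padding, dilation), _out_size(w, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    xg = xp.reshape(n, groups, cin_g, xp.shape[2], xp.shape[3])
    out = np.zeros((n, cout, ho, wo), dtype=np.float32)
    wd = weight.data
    for ci in range(cin_g):
        for ki in range(kh):
            for kj in range(kw):
                a, b = ki * dilation, kj * dilation
                sl = xg[:, :, ci, a:a + stride * (ho - 1) + 1:stride,
                        b:b + stride * (wo - 1) + 1:stride]
                out += wd[:, ci, ki, kj].reshape(1, cout, 1, 1) * sl
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)

    prev = (x, weight) + ((bias,) if bias is not None else ())
    needs = grad_enabled() and any(p.requires_grad for p in prev)
    res = Tensor(out, requires_grad=needs, _prev=prev if needs else ())
    if needs:
        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            dw = np.zeros_like(wd) if weight.requires_grad else None
            dxg = np.zeros_like(xg) if x.requires_grad else None
            for ci in range(cin_g):
                for ki in range(kh):
                    for kj in range(kw):
                        a, b = ki * dilation, kj * dilation
                        isl = (slice(None), slice(None), ci,
                               slice(a, a + stride * (ho - 1) + 1, stride),
                               slice(b, b + stride * (wo - 1) + 1, stride))
                        if dw is not None:
                            dw[:, ci, ki, kj] = (g * xg[isl]).sum(axis=(0, 2, 3))
                        if dxg is not None:
                            dxg[isl] += wd[:, ci, ki, kj].reshape(1, cout, 1, 1) * g
            if dw is not None:
                weight._accumulate(dw)
            if dxg is not None:
                dxp = dxg.reshape(n, c, xp.shape[2], xp.shape[3])
                if padding:
                    dxp = dxp[:, :, padding:padding + h, padding:padding + w]
                x._accumulate(np.ascontiguousarray(dxp))
        res._backward = backward
    return res


def params_of(weight: Tensor, bias: Tensor | None) -> int:
    return weight.data.size + (bias.data.size if bias is not None else 0)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, align_corners=False convention."""
    key = (n_in, n_out)
    if key not in _interp_cache:
        A = np.zeros((n_out, n_in), dtype=np.float32)
        scale = n_in / n_out
        for o in range(n_out):
            src = (o + 0.5) * scale - 0.5
            src = min(max(src, 0.0), n_in - 1.0)
            i0 = int(np.floor(src))
            i1 = min(i0 + 1, n_in - 1)
            t = src - i0
            A[o, i0] += 1.0 - t
            A[o, i1] += t
        _interp_cache[key] = A
    return _interp_cache[key]


def interpolate_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize expressed as two 1-D linear maps."""
    n, c, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        return x
    A = Tensor(_interp_matrix(h, out_h))          # (out_h, h)
    B = Tensor(_interp_matrix(w, out_w).T)        # (w, out_w)
    return (A @ x) @ B


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Transpose-reshape channel permutation; bijective for C % groups == 0."""
    n, c, h, w = x.data.shape
    if c % groups:
        raise ValueError(f"channel_shuffle: {c} channels not divisible by {groups} groups")
    return (x.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Batch normalization over (N, H, W) as one primitive.

    Returns (out, batch_mean, batch_var) with the statistics as plain arrays;
    memory-light: only the normalized map is retained for backward.
    """
    xd = x.data
    n, c = xd.shape[:2]
    axes = (0, 2, 3)
    m = xd.size // c
    mu = xd.mean(axis=axes, keepdims=True)
    var = np.square(xd).mean(axis=axes, keepdims=True) - mu * mu
    var = np.maximum(var, 0.0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    prev = (x, gamma, beta)
    needs = grad_enabled() and any(p.requires_grad for p in prev)
    res = Tensor(out, requires_grad=needs, _prev=prev if needs else ())
    if needs:
        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            gx = g * xhat
            if gamma.requires_grad:
                gamma._accumulate(gx.sum(axis=axes))
            if x.requires_grad:
                gm = g.mean(axis=axes, keepdims=True)
                gxm = gx.mean(axis=axes, keepdims=True)
                dx = (gamma.data.reshape(1, c, 1, 1) * inv) * (g - gm - xhat * gxm)
                x._accumulate(dx.astype(np.float32, copy=False))
        res._backward = backward
    return res, mu.reshape(-1), var.reshape(-1)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))   # constant shift
    z = x - m
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return log_softmax(x, axis).exp()
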