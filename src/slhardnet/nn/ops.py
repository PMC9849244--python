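"""Structured differentiable operations on N×C×H×W feature maps.

Convolution is evaluated as an im2col matrix product (one BLAS call per
batch), bilinear resizing and adaptive average pooling as separable row/column
interpolation matrices, which makes their adjoints exact transposed products.
"""

from __future__ import annotations

import functools

import numpy as np

from .tensor import Tensor, _unbroadcast  # noqa: F401

__all__ = [
    "conv2d",
    "maxpool2d",
    "resize_bilinear",
    "adaptive_avg_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "batchnorm2d",
]


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(xp: np.ndarray, kh, kw, sh, sw, dh, dw, ho, wo):
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :, i * dh : i * dh + (ho - 1) * sh + 1 : sh,
                j * dw : j * dw + (wo - 1) * sw + 1 : sw,
            ]
    return cols.reshape(n, c * kh * kw, ho * wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0, dilation=1) -> Tensor:
    """2-D cross-correlation; ``padding`` may be an (ph, pw) pair."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    ho = (h + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    wo = (wd + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, ho, wo)
    w2 = w.data.reshape(co, -1)
    out = np.matmul(w2, cols)  # (n, co, ho*wo)
    if b is not None:
        out += b.data.reshape(1, co, 1)
    out = out.reshape(n, co, ho, wo)

    parents = (x, w) if b is None else (x, w, b)

    def back(g):
        go = g.reshape(n, co, ho * wo)
        if w.requires_grad:
            # one GEMM: fold the batch into the pixel axis
            go2 = go.transpose(1, 0, 2).reshape(co, n * ho * wo)
            cols_f = cols.transpose(1, 0, 2).reshape(c * kh * kw, n * ho * wo)
            gw = np.matmul(go2, cols_f.T)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(go.sum(axis=(0, 2)).reshape(b.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w2.T, go).reshape(n, c, kh, kw, ho, wo)
            gxp = np.zeros((n, c, h + 2 * ph, wd + 2 * pw), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * dh : i * dh + (ho - 1) * sh + 1 : sh,
                        j * dw : j * dw + (wo - 1) * sw + 1 : sw] += gcols[:, :, i, j]
            gx = gxp[:, :, ph : ph + h, pw : pw + wd] if (ph or pw) else gxp
            x._accumulate(gx)

    return Tensor._make(out, parents, back)


def maxpool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); trailing rows/cols
    that do not fill a window are dropped."""
    k = kernel
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    v = x.data[:, :, : ho * k, : wo * k]
    windows = v.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, ho, wo, k * k)
    idx = np.argmax(flat, axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def back(g):
        buf = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        buf = buf.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, : ho * k, : wo * k] = buf.reshape(n, c, ho * k, wo * k)
        x._accumulate(gx)

    return Tensor._make(out, (x,), back)


@functools.lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


@functools.lru_cache(maxsize=256)
def _avg_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D adaptive-average-pooling matrix (equal-coverage bins)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-(i + 1) * n_in // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def _separable_resize(x: Tensor, ry: np.ndarray, rx: np.ndarray) -> Tensor:
    out = np.matmul(ry, x.data)
    out = np.matmul(out, rx.T)

    def back(g):
        gx = np.matmul(ry.T, g)
        gx = np.matmul(gx, rx)
        x._accumulate(gx)

    return Tensor._make(out, (x,), back)


def resize_bilinear(x: Tensor, size) -> Tensor:
    ho, wo = _pair(size)
    h, w = x.data.shape[-2:]
    if (ho, wo) == (h, w):
        return x
    return _separable_resize(x, _interp_matrix(h, ho), _interp_matrix(w, wo))


def adaptive_avg_pool2d(x: Tensor, size) -> Tensor:
    ho, wo = _pair(size)
    h, w = x.data.shape[-2:]
    return _separable_resize(x, _avg_matrix(h, ho), _avg_matrix(w, wo))


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    return x.reshape(n, c, h * w).max(axis=2, keepdims=True).reshape(n, c, 1, 1)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are updated in place in training mode.
    """
    n, c, h, w = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased estimate feeds the running buffer, biased one the batch
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def back(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(1, c, 1, 1)
            if training:
                m = n * h * w
                invr = inv.reshape(1, c, 1, 1)
                sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - sum_g / m - xhat * sum_gx / m) * invr
            else:
                gx = gxhat * inv.reshape(1, c, 1, 1)
            x._accumulate(gx)

    return Tensor._make(out, (x, gamma, beta), back)
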