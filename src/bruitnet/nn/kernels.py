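"""Numba-fused kernels for the memory-bound layer arithmetic.

BLAS handles the convolution GEMMs; these kernels fuse the per-channel
batch-norm statistics/normalization and the Adam update into single passes
so float32 training is not dominated by temporary-array traffic. All
kernels operate on contiguous views; the float64 gradient-check path in
the tests bypasses them (the layers fall back to NumPy for non-float32
input).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bn_stats",
    "bn_forward",
    "bn_backward",
    "adam_update",
    "conv_gather",
    "conv_scatter",
]


@njit(cache=True, fastmath=True, boundscheck=False)
def conv_gather(x):
    """im2col for a 3×3 same-padding conv on channels-last input.

    (N, H, W, C) → (N, H, W, 9, C); out-of-image taps stay zero.
    """
    n, h, w, c = x.shape
    cols = np.zeros((n, h, w, 9, c), dtype=np.float32)
    for nn in range(n):
        for i in range(h):
            for di in range(3):
                ii = i + di - 1
                if ii < 0 or ii >= h:
                    continue
                for j in range(w):
                    for dj in range(3):
                        jj = j + dj - 1
                        if jj < 0 or jj >= w:
                            continue
                        src = x[nn, ii, jj]
                        dst = cols[nn, i, j, di * 3 + dj]
                        for cc in range(c):
                            dst[cc] = src[cc]
    return cols


@njit(cache=True, fastmath=True, boundscheck=False)
def conv_scatter(dcols):
    """col2im adjoint of :func:`conv_gather`: (N, H, W, 9, C) → (N, H, W, C)."""
    n, h, w, _, c = dcols.shape
    dx = np.zeros((n, h, w, c), dtype=np.float32)
    for nn in range(n):
        for i in range(h):
            for di in range(3):
                ii = i + di - 1
                if ii < 0 or ii >= h:
                    continue
                for j in range(w):
                    for dj in range(3):
                        jj = j + dj - 1
                        if jj < 0 or jj >= w:
                            continue
                        src = dcols[nn, i, j, di * 3 + dj]
                        dst = dx[nn, ii, jj]
                        for cc in range(c):
                            dst[cc] += src[cc]
    return dx


@njit(cache=True, fastmath=True)
def bn_stats(x2d):
    """Per-channel mean and (biased) variance of an (M, C) float32 array."""
    m, c = x2d.shape
    s1 = np.zeros(c, dtype=np.float64)
    s2 = np.zeros(c, dtype=np.float64)
    for i in range(m):
        row = x2d[i]
        for j in range(c):
            v = row[j]
            s1[j] += v
            s2[j] += v * v
    mean = (s1 / m).astype(np.float32)
    var = (s2 / m - (s1 / m) ** 2).astype(np.float32)
    return mean, np.maximum(var, 0.0)


@njit(cache=True, fastmath=True)
def bn_forward(x2d, mean, inv, gamma, beta):
    """Fused normalize + affine; returns (y, xhat)."""
    m, c = x2d.shape
    y = np.empty_like(x2d)
    xhat = np.empty_like(x2d)
    for i in range(m):
        for j in range(c):
            h = (x2d[i, j] - mean[j]) * inv[j]
            xhat[i, j] = h
            y[i, j] = gamma[j] * h + beta[j]
    return y, xhat


@njit(cache=True, fastmath=True)
def bn_backward(xhat2d, dy2d, gamma, inv, batch_mode):
    """Fused batch-norm backward; returns (dx, dgamma, dbeta)."""
    m, c = xhat2d.shape
    dgamma = np.zeros(c, dtype=np.float64)
    dbeta = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            dgamma[j] += dy2d[i, j] * xhat2d[i, j]
            dbeta[j] += dy2d[i, j]
    dx = np.empty_like(dy2d)
    if batch_mode:
        mu_dy = (dbeta / m).astype(np.float32)
        mu_dyx = (dgamma / m).astype(np.float32)
        for i in range(m):
            for j in range(c):
                dx[i, j] = (
                    gamma[j]
                    * inv[j]
                    * (dy2d[i, j] - mu_dy[j] - xhat2d[i, j] * mu_dyx[j])
                )
    else:
        for i in range(m):
            for j in range(c):
                dx[i, j] = gamma[j] * inv[j] * dy2d[i, j]
    return dx, dgamma.astype(np.float32), dbeta.astype(np.float32)


@njit(cache=True, fastmath=True)
def adam_update(p, g, m, v, lr, beta1, beta2, eps, bias1, bias2):
    """In-place fused Adam step over flat float32 arrays."""
    for i in range(p.size):
        gi = g[i]
        m[i] += (1.0 - beta1) * (gi - m[i])
        v[i] += (1.0 - beta2) * (gi * gi - v[i])
        p[i] -= lr * (m[i] / bias1) / (np.sqrt(v[i] / bias2) + eps)
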