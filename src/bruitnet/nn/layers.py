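"""Minimal seeded NumPy layers with exact backpropagation.

Conventions: convolutional tensors are channels-last ``(N, H, W, C)`` with
H the mel axis and W the time axis; recurrent tensors are ``(N, T, D)``.
Convolution is 3×3, stride 1, zero padding 1 ("same"), realized as im2col
+ one BLAS GEMM per direction; channels-last keeps the patch
gather/scatter as contiguous block copies, which is what makes single-core
training tractable. All parameters and activations are float32; every
layer's backward pass is verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "TimeUnfold",
    "TimeAvgPool",
    "Dense",
    "BiGRU",
    "BiLSTM",
]

F32 = np.float32


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs.

    ``params`` and ``grads`` are parallel dicts of float32 arrays; layers
    without parameters leave them empty.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3×3 same-padding convolution, He-initialized.

    im2col + GEMM in channels-last layout: patches are gathered with nine
    contiguous block copies into ``cols`` of shape (N·H·W, 9·C) — column
    order (ki, kj, c) — and multiplied by the (9·C, out) weight; the
    backward pass scatters ``dcols`` back with nine block adds.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * 9
        self.params["W"] = (
            rng.standard_normal((9 * in_ch, out_ch)) * np.sqrt(2.0 / fan_in)
        ).astype(F32)
        self.params["b"] = np.zeros(out_ch, dtype=F32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if x.dtype == F32 and x.flags.c_contiguous:
            from .kernels import conv_gather

            cols = conv_gather(x).reshape(n * h * w, 9 * c)
        else:
            xp = np.zeros((n, h + 2, w + 2, c), dtype=x.dtype)
            xp[:, 1 : 1 + h, 1 : 1 + w] = x
            cols = np.empty((n, h, w, 9, c), dtype=x.dtype)
            for di in range(3):
                for dj in range(3):
                    cols[:, :, :, di * 3 + dj, :] = xp[:, di : di + h, dj : dj + w]
            cols = cols.reshape(n * h * w, 9 * c)
        y = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, (n, h, w, c))
        return y.reshape(n, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c) = self._cache
        dyf = np.ascontiguousarray(dy).reshape(n * h * w, self.out_ch)
        self.grads["W"] = cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].T).reshape(n, h, w, 9, c)
        self._cache = None
        if dcols.dtype == F32:
            from .kernels import conv_scatter

            return conv_scatter(dcols)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dy.dtype)
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h, dj : dj + w] += dcols[:, :, :, di * 3 + dj, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats.

    Channels-last: the channel axis is the trailing one.
    """

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=F32)
        self.params["beta"] = np.zeros(ch, dtype=F32)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        fast = x.dtype == F32 and x.flags.c_contiguous
        shape = x.shape
        if train:
            if fast:
                from .kernels import bn_stats

                mean, var = bn_stats(x.reshape(-1, shape[-1]))
            else:
                axes = tuple(range(x.ndim - 1))
                mean = x.mean(axis=axes)
                var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        if fast:
            from .kernels import bn_forward

            y2, xhat2 = bn_forward(
                x.reshape(-1, shape[-1]), mean.astype(F32), inv,
                self.params["gamma"], self.params["beta"],
            )
            # in eval mode the statistics are constants, so the gradient is
            # a plain affine scale; tag the cache with the mode used
            self._cache = ("batch" if train else "eval", xhat2, inv, shape)
            return y2.reshape(shape)
        xhat = (x - mean) * inv
        self._cache = ("batch" if train else "eval", xhat, inv, shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mode, xhat, inv, shape = self._cache
        if dy.dtype == F32 and xhat.dtype == F32:
            from .kernels import bn_backward

            dy2 = np.ascontiguousarray(dy).reshape(-1, shape[-1])
            dx2, dgamma, dbeta = bn_backward(
                xhat.reshape(-1, shape[-1]), dy2, self.params["gamma"],
                inv.astype(F32), mode == "batch",
            )
            self.grads["gamma"] = dgamma
            self.grads["beta"] = dbeta
            self._cache = None
            return dx2.reshape(shape)
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        if mode == "eval":
            dx = dxhat * inv
        else:
            dx = (
                dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            ) * inv
        self._cache = None
        return dx.astype(dy.dtype)


class ReLU(Layer):
    """Elementwise rectifier; shape-agnostic."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2×2 max pooling, stride 2, floor semantics (odd trailing row/col dropped)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
        y = xc.max(axis=(2, 4))
        mask = xc == y[:, :, None, :, None, :]
        # ties share the gradient so the pool stays finite-difference exact
        counts = mask.sum(axis=(2, 4), keepdims=True)
        self._cache = ((mask / counts).astype(x.dtype), x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, (n, h, w, c) = self._cache
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, : h2 * 2, : w2 * 2] = (
            mask * dy[:, :, None, :, None, :]
        ).reshape(n, h2 * 2, w2 * 2, c)
        self._cache = None
        return dx


class GlobalAvgPool2d(Layer):
    """(N, H, W, C) → (N, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return (np.broadcast_to(dy[:, None, None, :], (n, h, w, c)) / (h * w)).astype(
            dy.dtype
        )


class TimeUnfold(Layer):
    """(N, H, W, C) → (N, T=W, H·C): time steps of flattened freq×channel features."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        n, h, w, c = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, w, h * c)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.ascontiguousarray(
            dy.reshape(n, w, h, c).transpose(0, 2, 1, 3)
        )


class TimeAvgPool(Layer):
    """(N, T, D) → (N, D) mean over time."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, d = self._shape
        return np.broadcast_to(dy[:, None, :], (n, t, d)) / t


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = (
            rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        ).astype(F32)
        self.params["b"] = np.zeros(out_dim, dtype=F32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _GRUCell:
    """Single-direction GRU; gate order (z, r, h) in the fused weight."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator) -> None:
        s = np.sqrt(1.0 / d_h)
        self.params = {
            "W": (rng.uniform(-s, s, (d_in, 3 * d_h))).astype(F32),
            "U": (rng.uniform(-s, s, (d_h, 3 * d_h))).astype(F32),
            "b": np.zeros(3 * d_h, dtype=F32),
        }
        self.d_h = d_h

    def run(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        n, t, _ = x.shape
        dh = self.d_h
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, dh), dtype=x.dtype)
        out = np.empty((n, t, dh), dtype=x.dtype)
        cache = []
        xw = x @ W + b  # precompute input contributions for all steps
        for i in range(t):
            hu = h @ U
            z = _sigmoid(xw[:, i, :dh] + hu[:, :dh])
            r = _sigmoid(xw[:, i, dh : 2 * dh] + hu[:, dh : 2 * dh])
            hh = np.tanh(xw[:, i, 2 * dh :] + r * hu[:, 2 * dh :])
            h_new = (1 - z) * h + z * hh
            if train:
                cache.append((h, z, r, hh, hu[:, 2 * dh :]))
            out[:, i] = h_new
            h = h_new
        return out, cache

    def backprop(
        self, x: np.ndarray, dout: np.ndarray, cache: list
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        n, t, d_in = x.shape
        dh = self.d_h
        W, U = self.params["W"], self.params["U"]
        dx = np.zeros_like(x)
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(3 * dh, dtype=np.float64)
        dh_next = np.zeros((n, dh), dtype=x.dtype)
        for i in reversed(range(t)):
            h_prev, z, r, hh, uh_h = cache[i]
            dtotal = dout[:, i] + dh_next
            dz = dtotal * (hh - h_prev) * z * (1 - z)
            dhh = dtotal * z * (1 - hh * hh)
            dr = dhh * uh_h * r * (1 - r)
            dgates = np.concatenate([dz, dr, dhh], axis=1)
            dx[:, i] = dgates @ W.T
            dW += x[:, i].T @ dgates
            db += dgates.sum(axis=0)
            # h_prev feeds: the (1-z) carry, the U projections of z and r,
            # and the candidate through r ∘ (h_prev U_h)
            du_in = np.concatenate([dz, dr, dhh * r], axis=1)
            dU += h_prev.T @ du_in
            dh_next = dtotal * (1 - z) + du_in @ U.T
        return dx, {"W": dW, "U": dU, "b": db.astype(x.dtype)}


class _LSTMCell:
    """Single-direction LSTM; gate order (i, f, o, g) in the fused weight."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator) -> None:
        s = np.sqrt(1.0 / d_h)
        self.params = {
            "W": (rng.uniform(-s, s, (d_in, 4 * d_h))).astype(F32),
            "U": (rng.uniform(-s, s, (d_h, 4 * d_h))).astype(F32),
            "b": np.zeros(4 * d_h, dtype=F32),
        }
        # forget-gate bias 1: standard stabilization
        self.params["b"][d_h : 2 * d_h] = 1.0
        self.d_h = d_h

    def run(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        n, t, _ = x.shape
        dh = self.d_h
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, dh), dtype=x.dtype)
        c = np.zeros((n, dh), dtype=x.dtype)
        out = np.empty((n, t, dh), dtype=x.dtype)
        cache = []
        xw = x @ W + b
        for step in range(t):
            gates = xw[:, step] + h @ U
            i_g = _sigmoid(gates[:, :dh])
            f_g = _sigmoid(gates[:, dh : 2 * dh])
            o_g = _sigmoid(gates[:, 2 * dh : 3 * dh])
            g_g = np.tanh(gates[:, 3 * dh :])
            c_new = f_g * c + i_g * g_g
            tc = np.tanh(c_new)
            h_new = o_g * tc
            if train:
                cache.append((h, c, i_g, f_g, o_g, g_g, tc))
            out[:, step] = h_new
            h, c = h_new, c_new
        return out, cache

    def backprop(
        self, x: np.ndarray, dout: np.ndarray, cache: list
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        n, t, _ = x.shape
        dh = self.d_h
        W, U = self.params["W"], self.params["U"]
        dx = np.zeros_like(x)
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * dh, dtype=np.float64)
        dh_next = np.zeros((n, dh), dtype=x.dtype)
        dc_next = np.zeros((n, dh), dtype=x.dtype)
        for step in reversed(range(t)):
            h_prev, c_prev, i_g, f_g, o_g, g_g, tc = cache[step]
            dtotal = dout[:, step] + dh_next
            do = dtotal * tc * o_g * (1 - o_g)
            dc = dtotal * o_g * (1 - tc * tc) + dc_next
            di = dc * g_g * i_g * (1 - i_g)
            df = dc * c_prev * f_g * (1 - f_g)
            dg = dc * i_g * (1 - g_g * g_g)
            dgates = np.concatenate([di, df, do, dg], axis=1)
            dx[:, step] = dgates @ W.T
            dW += x[:, step].T @ dgates
            dU += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            dh_next = dgates @ U.T
            dc_next = dc * f_g
        return dx, {"W": dW, "U": dU, "b": db.astype(x.dtype)}


class _BiRecurrent(Layer):
    """Bidirectional wrapper: forward and time-reversed cells, outputs concatenated."""

    cell_cls: type

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_h = d_h
        self.fwd = self.cell_cls(d_in, d_h, rng)
        self.bwd = self.cell_cls(d_in, d_h, rng)
        for name, arr in self.fwd.params.items():
            self.params[f"fwd_{name}"] = arr
        for name, arr in self.bwd.params.items():
            self.params[f"bwd_{name}"] = arr

    def _sync(self) -> None:
        # optimizer updates self.params in place via views; keep cells aligned
        for name in self.fwd.params:
            self.fwd.params[name] = self.params[f"fwd_{name}"]
            self.bwd.params[name] = self.params[f"bwd_{name}"]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._sync()
        x = np.ascontiguousarray(x)
        out_f, cache_f = self.fwd.run(x, True)
        xr = x[:, ::-1]
        out_b, cache_b = self.bwd.run(xr, True)
        out_b = out_b[:, ::-1]
        self._cache = (x, xr, cache_f, cache_b)
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, xr, cache_f, cache_b = self._cache
        dh = self.d_h
        dx_f, g_f = self.fwd.backprop(x, np.ascontiguousarray(dy[:, :, :dh], dtype=x.dtype), cache_f)
        dx_b, g_b = self.bwd.backprop(
            xr, np.ascontiguousarray(dy[:, ::-1, dh:], dtype=x.dtype), cache_b
        )
        for name, g in g_f.items():
            self.grads[f"fwd_{name}"] = g
        for name, g in g_b.items():
            self.grads[f"bwd_{name}"] = g
        self._cache = None
        return dx_f + dx_b[:, ::-1]


class BiGRU(_BiRecurrent):
    cell_cls = _GRUCell


class BiLSTM(_BiRecurrent):
    cell_cls = _LSTMCell
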