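"""Layers of the CNN-TCN encoder, with explicit backward passes.

Shape conventions:
  - band blocks: (N, bands, time, muscle_channels)
  - TCN sequences: (N, features, time)
  - dense features: (N, features)
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_DTYPE, Module, Parameter, uniform_init


class PerBandConv(Module):
    """Per-band temporal convolution: each band has its own kx1 kernel
    (single in/out channel, bias on), applied along time to every muscle
    column independently.  This is the frequency-partitioned ('depthwise')
    stage of the time-frequency branch."""

    def __init__(self, bands: int, kernel: int = 3, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.weight = Parameter(uniform_init(rng, (bands, kernel), kernel, dtype))
        self.bias = Parameter(np.zeros(bands, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        t_out = x.shape[2] - k + 1
        w = self.weight.data
        y = np.tile(self.bias.data[None, :, None, None], (x.shape[0], 1, t_out, x.shape[3]))
        for j in range(k):
            y += w[None, :, j, None, None] * x[:, :, j : j + t_out, :]
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, k = self._x, self.kernel
        t_out = dy.shape[2]
        dx = np.zeros_like(x)
        w = self.weight.data
        for j in range(k):
            self.weight.grad[:, j] += np.einsum(
                "nbtc,nbtc->b", dy, x[:, :, j : j + t_out, :], optimize=True
            )
            dx[:, :, j : j + t_out, :] += w[None, :, j, None, None] * dy
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dx


class PerBandConvPool(Module):
    """Per-band kx1 conv followed by size-p average pooling, computed fused.

    Averaging p consecutive conv outputs is itself a (k+p-1)-tap strided
    convolution, so the pooled sequence is computed directly with stride p —
    identical function and parameters to PerBandConv + AvgPoolTime (the
    unfused pair remains available via ``forward_unfused`` for stage-shape
    probes), at a quarter of the memory traffic."""

    def __init__(self, bands: int, kernel: int = 3, pool: int = 4, rng=None,
                 dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.pool = pool
        self.weight = Parameter(uniform_init(rng, (bands, kernel), kernel, dtype))
        self.bias = Parameter(np.zeros(bands, dtype=dtype))

    def _taps(self) -> np.ndarray:
        w = self.weight.data
        k, p = self.kernel, self.pool
        c = np.zeros((w.shape[0], k + p - 1), dtype=w.dtype)
        for j in range(p):
            c[:, j : j + k] += w
        return c / p

    def out_len(self, t_in: int) -> int:
        return (t_in - self.kernel + 1) // self.pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.kernel, self.pool
        t_out = self.out_len(x.shape[2])
        taps = self._taps()
        y = np.tile(self.bias.data[None, :, None, None],
                    (x.shape[0], 1, t_out, x.shape[3]))
        span = p * (t_out - 1) + 1
        for m in range(k + p - 1):
            y += taps[None, :, m, None, None] * x[:, :, m : m + span : p, :]
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, k, p = self._x, self.kernel, self.pool
        t_out = dy.shape[2]
        span = p * (t_out - 1) + 1
        taps = self._taps()
        dtaps = np.empty_like(taps)
        dx = np.zeros_like(x)
        for m in range(k + p - 1):
            sl = x[:, :, m : m + span : p, :]
            dtaps[:, m] = np.einsum("nbtc,nbtc->b", dy, sl, optimize=True)
            dx[:, :, m : m + span : p, :] += taps[None, :, m, None, None] * dy
        # chain rule through taps -> weights: w_k appears in taps j+k, j=0..p-1
        for kk in range(k):
            self.weight.grad[:, kk] += dtaps[:, kk : kk + p].sum(axis=1) / p
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dx

    def forward_unfused(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Reference path: explicit conv output then pooled output."""
        conv = PerBandConv.__new__(PerBandConv)
        conv.kernel = self.kernel
        conv.weight, conv.bias = self.weight, self.bias
        c = conv.forward(x)
        return c, AvgPoolTime(self.pool).forward(c)


class AvgPoolTime(Module):
    """Average pooling along the time axis (axis 2), size == stride.
    A trailing remainder shorter than the pool is discarded, which is what
    produces the 1198->299 and 297->74 rows of the shape ladder."""

    def __init__(self, size: int = 4):
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.size
        t_out = x.shape[2] // s
        self._in_shape = x.shape
        xr = x[:, :, : t_out * s, :].reshape(x.shape[0], x.shape[1], t_out, s, x.shape[3])
        return xr.mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.size
        n, b, t_out, c = dy.shape
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :, : t_out * s, :] = np.repeat(dy / s, s, axis=2)
        return dx


class MaxPoolTime(Module):
    """Max pooling along axis 1 of a (N, time, channels) block."""

    def __init__(self, size: int = 4):
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.size
        t_out = x.shape[1] // s
        self._in_shape = x.shape
        xr = x[:, : t_out * s, :].reshape(x.shape[0], t_out, s, x.shape[2])
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.size
        n, t_out, c = dy.shape
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dxr = dx[:, : t_out * s, :].reshape(n, t_out, s, c)
        ni, ti, ci = np.ogrid[:n, :t_out, :c]
        dxr[ni, ti, self._argmax, ci] = dy
        dx[:, : t_out * s, :] = dxr.reshape(n, t_out * s, c)
        return dx


class BandMixConv(Module):
    """Aggregation convolution across bands: in_bands -> out_bands with a
    kx1 temporal kernel and bias, mixing the per-band features while the
    muscle columns stay independent."""

    def __init__(self, in_bands: int, out_bands: int, kernel: int = 3, rng=None,
                 dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        fan_in = in_bands * kernel
        self.weight = Parameter(uniform_init(rng, (out_bands, in_bands, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_bands, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        t_out = x.shape[2] - k + 1
        w = self.weight.data
        y = np.tile(self.bias.data[None, :, None, None], (x.shape[0], 1, t_out, x.shape[3]))
        for j in range(k):
            y += np.einsum("oi,nitc->notc", w[:, :, j], x[:, :, j : j + t_out, :],
                           optimize=True)
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, k = self._x, self.kernel
        t_out = dy.shape[2]
        dx = np.zeros_like(x)
        w = self.weight.data
        for j in range(k):
            self.weight.grad[:, :, j] += np.einsum(
                "notc,nitc->oi", dy, x[:, :, j : j + t_out, :], optimize=True
            )
            dx[:, :, j : j + t_out, :] += np.einsum(
                "oi,notc->nitc", w[:, :, j], dy, optimize=True
            )
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm(Module):
    """Batch normalization over all axes except the feature axis (axis 1),
    affine (2 trainable scalars per feature), with running statistics for
    inference.

    Besides the usual exponential moving average, the layer supports a
    precise-recalibration mode: between ``start_calibration`` and
    ``finish_calibration`` every training-mode forward accumulates exact
    batch statistics, and the running statistics are replaced by their
    aggregate.  Deep stacks trained for only a handful of mini-batches
    would otherwise evaluate against badly stale statistics."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE):
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._collect = False

    def start_calibration(self) -> None:
        self._collect = True
        self._cal_sum = 0.0
        self._cal_sumsq = 0.0
        self._cal_n = 0

    def finish_calibration(self) -> None:
        if self._cal_n:
            mean = self._cal_sum / self._cal_n
            var = np.maximum(self._cal_sumsq / self._cal_n - mean**2, 0.0)
            self.running_mean = mean.astype(self.running_mean.dtype)
            self.running_var = var.astype(self.running_var.dtype)
        self._collect = False

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shape = self._bshape(x.ndim)
        axes = tuple(i for i in range(x.ndim) if i != 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._collect:
                m = x.size // x.shape[1]
                self._cal_sum = self._cal_sum + mean * m
                self._cal_sumsq = self._cal_sumsq + (var + mean**2) * m
                self._cal_n += m
            else:
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mean
                ).astype(self.running_mean.dtype)
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var
                ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._train = train
        self._xhat, self._std, self._axes = xhat, std, axes
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = self._bshape(dy.ndim)
        xhat, std, axes = self._xhat, self._std, self._axes
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data.reshape(shape)
        if not self._train:
            return dxhat / std.reshape(shape)
        m = dy.size // dy.shape[1]
        sum_dxhat = dxhat.sum(axis=axes).reshape(shape)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes).reshape(shape)
        return (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m) / std.reshape(shape)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * dy, dy)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, 0.0, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, 0.0, dy)


class Sigmoid(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class CausalConv1d(Module):
    """Dilated causal 1-D convolution on (N, channels, time).

    Left padding of (k-1)*d followed by 'chomping' the right overhang: the
    implementation pads left only, so output step t never sees input steps
    after t."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, dilation: int = 1,
                 rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.dilation = dilation
        fan_in = c_in * kernel
        self.weight = Parameter(uniform_init(rng, (c_out, c_in, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        xp = np.pad(x, ((0, 0), (0, 0), (pad, 0)))
        t = x.shape[2]
        w = self.weight.data
        y = np.tile(self.bias.data[None, :, None], (x.shape[0], 1, t))
        for j in range(k):
            y += np.einsum("oi,nit->not", w[:, :, j], xp[:, :, j * d : j * d + t],
                           optimize=True)
        self._xp, self._t = xp, t
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        xp, t = self._xp, self._t
        dxp = np.zeros_like(xp)
        w = self.weight.data
        for j in range(k):
            self.weight.grad[:, :, j] += np.einsum(
                "not,nit->oi", dy, xp[:, :, j * d : j * d + t], optimize=True
            )
            dxp[:, :, j * d : j * d + t] += np.einsum(
                "oi,not->nit", w[:, :, j], dy, optimize=True
            )
        self.bias.grad += dy.sum(axis=(0, 2))
        return dxp[:, :, pad:]


class PointwiseConv1d(Module):
    """1x1 convolution on (N, channels, time); the residual width-matcher."""

    def __init__(self, c_in: int, c_out: int, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(uniform_init(rng, (c_out, c_in), c_in, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return (
            np.einsum("oi,nit->not", self.weight.data, x, optimize=True)
            + self.bias.data[None, :, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("not,nit->oi", dy, self._x, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2))
        return np.einsum("oi,not->nit", self.weight.data, dy, optimize=True)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(uniform_init(rng, (f_out, f_in), f_in, dtype))
        self.bias = Parameter(np.zeros(f_out, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += dy2.T @ x2
        self.bias.grad += dy2.sum(axis=0)
        return dy @ self.weight.data


class Dropout(Module):
    """Inverted dropout; identity at evaluation time.  The mask RNG is owned
    by the training loop and injected via ``set_rng`` so runs are seeded."""

    def __init__(self, p: float = 0.3):
        self.p = p
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.steps = list(modules)

    def forward(self, x, train: bool = False):
        for m in self.steps:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy):
        for m in reversed(self.steps):
            dy = m.backward(dy)
        return dy
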