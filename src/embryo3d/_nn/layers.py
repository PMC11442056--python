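"""Layer primitives with explicit forward/backward passes.

Conventions: activations are float64 arrays shaped ``(N, C, *spatial)`` where
spatial has 2 (images) or 3 (volumes) axes. All convolutions are stride 1;
spatial reduction is done by :class:`AvgPool`. Backward passes are pure
tensordot/reshape arithmetic — no scatter ops — which keeps them fast and
bit-deterministic on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _as_tuple(k, n: int) -> tuple[int, ...]:
    if np.isscalar(k):
        return (int(k),) * n
    t = tuple(int(v) for v in k)
    if len(t) != n:
        raise ValueError(f"expected {n} entries, got {t}")
    return t


class Conv(Layer):
    """Stride-1 cross-correlation with zero padding, for 2-D or 3-D inputs.

    Weight shape is ``(c_out, c_in, *kernel)``. He-uniform init.
    """

    def __init__(self, ndim: int, c_in: int, c_out: int, kernel, pad=None,
                 rng: np.random.Generator | None = None):
        self.ndim = ndim
        self.kernel = _as_tuple(kernel, ndim)
        self.pad = _as_tuple(pad, ndim) if pad is not None else tuple(k // 2 for k in self.kernel)
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * int(np.prod(self.kernel))
        bound = np.sqrt(6.0 / fan_in)
        self.w = Param(rng.uniform(-bound, bound, size=(c_out, c_in, *self.kernel)))
        self.b = Param(np.zeros(c_out))
        self._x_padded: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def _spatial_axes(self, arr):
        return tuple(range(2, 2 + self.ndim))

    def forward(self, x, train):
        nsp = self.ndim
        pads = ((0, 0), (0, 0)) + tuple((p, p) for p in self.pad)
        xp = np.pad(x, pads)
        self._x_padded = xp if train else None
        win = sliding_window_view(xp, self.kernel, axis=tuple(range(2, 2 + nsp)))
        # win: (N, C, *S_out, *K) ; contract C and K against w (F, C, *K)
        axes_win = (1,) + tuple(range(2 + nsp, 2 + 2 * nsp))
        axes_w = (1,) + tuple(range(2, 2 + nsp))
        y = np.tensordot(win, self.w.value, axes=(axes_win, axes_w))
        y = np.moveaxis(y, -1, 1)
        y += self.b.value.reshape((1, -1) + (1,) * nsp)
        return y

    def backward(self, dy):
        nsp = self.ndim
        xp = self._x_padded
        if xp is None:
            raise RuntimeError("backward called without a training forward pass")
        win = sliding_window_view(xp, self.kernel, axis=tuple(range(2, 2 + nsp)))
        sum_axes = (0,) + tuple(range(2, 2 + nsp))
        self.b.grad += dy.sum(axis=sum_axes)
        # dW[f, c, *k] = sum_{n, s} x_pad[n, c, s + k] * dy[n, f, s]
        dw = np.tensordot(dy, win, axes=(sum_axes, sum_axes))
        self.w.grad += dw
        # dX = full correlation of dy with spatially flipped weights
        full_pads = ((0, 0), (0, 0)) + tuple(
            (k - 1 - p, k - 1 - p) for k, p in zip(self.kernel, self.pad)
        )
        dyp = np.pad(dy, full_pads)
        win_dy = sliding_window_view(dyp, self.kernel, axis=tuple(range(2, 2 + nsp)))
        wflip = self.w.value
        for ax in range(2, 2 + nsp):
            wflip = np.flip(wflip, axis=ax)
        axes_win = (1,) + tuple(range(2 + nsp, 2 + 2 * nsp))
        axes_w = (0,) + tuple(range(2, 2 + nsp))
        dx = np.tensordot(win_dy, wflip, axes=(axes_win, axes_w))
        return np.moveaxis(dx, -1, 1)


class BatchNorm(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        if train:
            self._cache = (xhat, inv_std, axes, shp)
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, dy):
        xhat, inv_std, axes, shp = self._cache
        m = dy.size // dy.shape[1]
        self.beta.grad += dy.sum(axis=axes)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        dxhat = dy * self.gamma.value.reshape(shp)
        t1 = m * dxhat
        t2 = dxhat.sum(axis=axes).reshape(shp)
        t3 = xhat * (dxhat * xhat).sum(axis=axes).reshape(shp)
        return (inv_std.reshape(shp) / m) * (t1 - t2 - t3)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool(Layer):
    """Non-overlapping average pooling; pool sizes clamp to the axis length.

    Trailing remainder rows/columns are cropped (sizes here are always chosen
    to divide evenly in practice).
    """

    def __init__(self, size):
        self.size = tuple(int(s) for s in size)
        self._cache = None

    def _effective(self, x):
        return tuple(min(s, d) for s, d in zip(self.size, x.shape[2:]))

    def forward(self, x, train):
        eff = self._effective(x)
        cropped_shape = tuple((d // s) * s for d, s in zip(x.shape[2:], eff))
        sl = (slice(None), slice(None)) + tuple(slice(0, c) for c in cropped_shape)
        xc = x[sl]
        new_shape = x.shape[:2]
        for d, s in zip(cropped_shape, eff):
            new_shape += (d // s, s)
        xr = xc.reshape(new_shape)
        axes = tuple(range(3, xr.ndim, 2)) if x.ndim == 4 else tuple(range(3, xr.ndim, 2))
        # mean over every second (block) axis
        block_axes = tuple(2 + 2 * i + 1 for i in range(len(eff)))
        y = xr.mean(axis=block_axes)
        if train:
            self._cache = (x.shape, eff, cropped_shape)
        return y

    def backward(self, dy):
        x_shape, eff, cropped_shape = self._cache
        scale = 1.0 / float(np.prod(eff))
        g = dy * scale
        for i, s in enumerate(eff):
            g = np.repeat(g, s, axis=2 + i)
        out = np.zeros(x_shape, dtype=g.dtype)
        sl = (slice(None), slice(None)) + tuple(slice(0, c) for c in cropped_shape)
        out[sl] = g
        return out


class Upsample(Layer):
    """Integer-factor nearest-neighbour upsampling."""

    def __init__(self, size):
        self.size = tuple(int(s) for s in size)

    def forward(self, x, train):
        y = x
        for i, s in enumerate(self.size):
            y = np.repeat(y, s, axis=2 + i)
        return y

    def backward(self, dy):
        g = dy
        for i, s in enumerate(self.size):
            ax = 2 + i
            d = g.shape[ax] // s
            new_shape = g.shape[:ax] + (d, s) + g.shape[ax + 1:]
            g = g.reshape(new_shape).sum(axis=ax + 1)
        return g


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / n_in)
        self.w = Param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class GlobalAvgPool(Layer):
    """(N, C, *spatial) -> (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        shape = self._shape
        m = int(np.prod(shape[2:]))
        g = (dy / m).reshape(shape[:2] + (1,) * (len(shape) - 2))
        return np.broadcast_to(g, shape).copy()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.params())
        return out

    def forward(self, x, train):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy
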