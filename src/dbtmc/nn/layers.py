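"""Layers with explicit forward/backward passes.

Conventions: 2D feature maps are (B, C, H, W); 3D maps are (B, C, D, H, W)
with D the through-plane (slice) axis.  All arithmetic is float32.
Caches needed for the backward pass are only stored when ``train=True``,
so full-size inference stays memory-lean.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_F)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_F)


class Conv2d(Layer):
    """'same'-padded strided 2D convolution via im2col and one matmul."""

    def __init__(self, c_in, c_out, kernel, stride=(1, 1), rng=None, bias=False):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        sh, sw = (stride, stride) if np.isscalar(stride) else stride
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("only odd kernel sizes are supported")
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw, self.sh, self.sw = kh, kw, sh, sw
        self.w = Param(_he_init(rng, (c_out, c_in, kh, kw), c_in * kh * kw))
        self.b = Param(np.zeros(c_out, dtype=_F)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_F)
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, :: self.sh, :: self.sw]
        _, _, ho, wo, _, _ = win.shape
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, -1
        )
        wm = self.w.value.reshape(self.c_out, -1)
        out = cols @ wm.T
        if self.b is not None:
            out += self.b.value
        out = out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dy):
        cols, x_shape, (ho, wo) = self._cache
        b, c, h, w = x_shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.w.grad += (dyf.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.w.value.reshape(self.c_out, -1)).reshape(
            b, ho, wo, c, self.kh, self.kw
        )
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=_F)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[
                    :,
                    :,
                    i : i + self.sh * (ho - 1) + 1 : self.sh,
                    j : j + self.sw * (wo - 1) + 1 : self.sw,
                ] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, ph : ph + h, pw : pw + w]


class IntraSliceConv3d(Layer):
    """k x k x 1 convolution: a 2D convolution applied to every slice."""

    def __init__(self, c_in, c_out, kernel=3, stride_inplane=1, rng=None, bias=False):
        self.conv = Conv2d(c_in, c_out, kernel, stride_inplane, rng=rng, bias=bias)
        self._bd = None

    def params(self):
        return self.conv.params()

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        self._bd = (b, d)
        xt = np.ascontiguousarray(x.transpose(0, 2, 1, 3, 4)).reshape(b * d, c, h, w)
        y = self.conv.forward(xt, train)
        _, co, ho, wo = y.shape
        return np.ascontiguousarray(
            y.reshape(b, d, co, ho, wo).transpose(0, 2, 1, 3, 4)
        )

    def backward(self, dy):
        b, d = self._bd
        _, co, _, ho, wo = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1, 3, 4)).reshape(
            b * d, co, ho, wo
        )
        dx = self.conv.backward(dyt)
        _, c, h, w = dx.shape
        return np.ascontiguousarray(
            dx.reshape(b, d, c, h, w).transpose(0, 2, 1, 3, 4)
        )


class InterSliceConv3d(Layer):
    """1 x 1 x k convolution along the slice axis (through-plane mixing)."""

    def __init__(self, c_in, c_out, kernel=3, stride_depth=1, rng=None, bias=False):
        self.conv = Conv2d(c_in, c_out, (kernel, 1), (stride_depth, 1), rng=rng,
                           bias=bias)
        self._shape = None

    def params(self):
        return self.conv.params()

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        self._shape = (b, c, d, h, w)
        xt = np.ascontiguousarray(x.transpose(0, 3, 4, 1, 2)).reshape(
            b * h * w, c, d, 1
        )
        y = self.conv.forward(xt, train)
        _, co, do, _ = y.shape
        return np.ascontiguousarray(
            y.reshape(b, h, w, co, do).transpose(0, 3, 4, 1, 2)
        )

    def backward(self, dy):
        b, c, d, h, w = self._shape
        _, co, do, _, _ = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 3, 4, 1, 2)).reshape(
            b * h * w, co, do, 1
        )
        dx = self.conv.backward(dyt)
        return np.ascontiguousarray(
            dx.reshape(b, h, w, c, d).transpose(0, 3, 4, 1, 2)
        )


class BatchNorm(Layer):
    """Per-channel batch normalization for (B, C, ...) inputs."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=_F))
        self.beta = Param(np.zeros(c, dtype=_F))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=_F)
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if train:
            self._cache = (xhat, invstd, axes, shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy):
        xhat, invstd, axes, shape = self._cache
        m = dy.size // dy.shape[1]
        self.dgamma_update(dy, xhat, axes)
        dxhat = dy * self.gamma.value.reshape(shape)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = (invstd.reshape(shape) / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(_F)

    def dgamma_update(self, dy, xhat, axes):
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """Max pooling with 'same'-style padding (pad = kernel // 2, value -inf)."""

    def __init__(self, kernel=3, stride=2):
        self.k, self.s = kernel, stride
        self._cache = None

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=_F)
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.s, :: self.s]
        _, _, ho, wo, _, _ = win.shape
        flat = win.reshape(b, c, ho, wo, -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, (b, c, h, w), (ho, wo), p)
        return np.ascontiguousarray(out)

    def backward(self, dy):
        arg, (b, c, h, w), (ho, wo), p = self._cache
        rows = arg // self.k + np.arange(ho)[:, None] * self.s
        cols = arg % self.k + np.arange(wo)[None, :] * self.s
        flatpos = rows * (w + 2 * p) + cols
        dxp = np.zeros((b, c, (h + 2 * p) * (w + 2 * p)), dtype=_F)
        bi = np.arange(b)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (bi, ci, flatpos), dy)
        dxp = dxp.reshape(b, c, h + 2 * p, w + 2 * p)
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w]


class MaxPool3dInPlane(Layer):
    """In-plane (k x k x 1) max pooling of a 3D feature map."""

    def __init__(self, kernel=3, stride=2):
        self.pool = MaxPool2d(kernel, stride)
        self._bd = None

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        self._bd = (b, d)
        xt = np.ascontiguousarray(x.transpose(0, 2, 1, 3, 4)).reshape(b * d, c, h, w)
        y = self.pool.forward(xt, train)
        _, co, ho, wo = y.shape
        return np.ascontiguousarray(
            y.reshape(b, d, co, ho, wo).transpose(0, 2, 1, 3, 4)
        )

    def backward(self, dy):
        b, d = self._bd
        _, co, _, ho, wo = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1, 3, 4)).reshape(
            b * d, co, ho, wo
        )
        dx = self.pool.backward(dyt)
        _, c, h, w = dx.shape
        return np.ascontiguousarray(
            dx.reshape(b, d, c, h, w).transpose(0, 2, 1, 3, 4)
        )


class GlobalAvgPool(Layer):
    """Mean over every axis but (batch, channel) -> (B, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes)

    def backward(self, dy):
        shape = self._shape
        n = int(np.prod(shape[2:]))
        dy_expanded = dy.reshape(shape[:2] + (1,) * (len(shape) - 2))
        return (np.broadcast_to(dy_expanded, shape) / n).astype(_F)


class Dropout(Layer):
    """Inverted dropout with a layer-owned seeded RNG stream."""

    def __init__(self, p=0.5, seed=0):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(_F) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        self.w = Param(_he_init(rng, (n_out, n_in), n_in))
        self.b = Param(np.zeros(n_out, dtype=_F))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=_F)
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value
        self._x = None
        return dx


class Add(Layer):
    """Residual addition of a main path and a shortcut path."""

    def __init__(self, main: Sequential, shortcut: Sequential | None):
        self.main = main
        self.shortcut = shortcut  # None means identity

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x, train=False):
        y = self.main.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return y + s

    def backward(self, dy):
        dx = self.main.backward(dy)
        if self.shortcut is None:
            dx = dx + dy
        else:
            dx = dx + self.shortcut.backward(dy)
        return dx
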