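"""Minimal convolutional network framework with hand-derived gradients.

Implements exactly the layer set needed by the super-resolution generator and
the Wasserstein critic: 3x3/1x1 convolutions (stride 1, via im2col), 2x2 max
pooling, stride-2 downsampling (a stride-1 convolution followed by
``Downsample2x`` reproduces a strided convolution exactly), 2x2 stride-2
transpose convolution, batch normalization, ReLU / leaky ReLU, fixed bilinear
2x upsampling, and an Adam optimizer.  Arrays are (N, C, H, W) in the module
precision ``DTYPE`` (float32).

Every layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. the output and returns the gradient w.r.t. the input, while
accumulating parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: working precision of the framework; float32 keeps the im2col matmuls in
#: cache-friendly territory without hurting training stability
DTYPE = np.float32

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "LeakyReLU",
    "MaxPool2x2", "Downsample2x", "ConvTranspose2x2", "UpsampleBilinear2x",
    "Sequential", "GlobalMean", "Adam", "clip_params",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


# --------------------------------------------------------------------------- #
# convolution
# --------------------------------------------------------------------------- #

def _conv2d_raw(x, w, pad):
    """Stride-1 cross-correlation of (N, C, H, W) with (O, C, k, k)."""
    x = np.ascontiguousarray(x, dtype=DTYPE)
    k = w.shape[2]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))   # N,C,H',W',k,k
    N, C, H, W = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(N * H * W, C * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T            # (NHW, O)
    return np.ascontiguousarray(out.reshape(N, H, W, -1)
                                .transpose(0, 3, 1, 2)), cols


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding for odd k (pad = k // 2)."""

    def __init__(self, c_in, c_out, k, rng, pad=None, bias=True):
        self.k, self.pad = k, (k // 2 if pad is None else pad)
        scale = np.sqrt(2.0 / (c_in * k * k))           # He initialization
        self.w = Param(rng.normal(0.0, scale, (c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        y, cols = _conv2d_raw(x, self.w.value, self.pad)
        if self.b is not None:
            y = y + self.b.value[None, :, None, None]
        self._cache = (x.shape, cols, y.shape)
        return y

    def backward(self, gy):
        x_shape, cols, y_shape = self._cache
        N, O, H, W = gy.shape
        g = gy.transpose(0, 2, 3, 1).reshape(N * H * W, O)
        self.w.grad += (g.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        # input gradient: correlate gy with spatially flipped, transposed kernels
        w_flip = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gx, _ = _conv2d_raw(gy, w_flip, self.k - 1 - self.pad)
        return gx


class ConvTranspose2x2(Layer):
    """2 x 2 transpose convolution with stride 2: each input pixel emits a
    2 x 2 output block."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.w = Param(rng.normal(0.0, scale, (c_in, c_out, 2, 2)))
        self.b = Param(np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        N, C, H, W = x.shape
        blocks = np.einsum("nchw,cokl->nohkwl", x, self.w.value)
        y = blocks.reshape(N, -1, 2 * H, 2 * W)
        return y + self.b.value[None, :, None, None]

    def backward(self, gy):
        x = self._x
        N, C, H, W = x.shape
        gb = gy.reshape(N, gy.shape[1], H, 2, W, 2)
        self.w.grad += np.einsum("nchw,nohkwl->cokl", x, gb)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return np.einsum("nohkwl,cokl->nchw", gb, self.w.value)


# --------------------------------------------------------------------------- #
# normalization / activations / resampling
# --------------------------------------------------------------------------- #

class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, std, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return gy * g / std[None, :, None, None]
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        gy_sum = gy.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        gyx_sum = (gy * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return (g / std[None, :, None, None]) * (
            gy - gy_sum / m - xhat * gyx_sum / m)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        idx, x_shape = self._cache
        N, C, H, W = x_shape
        g4 = np.zeros((N, C, H // 2, W // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g4, idx[..., None], gy[..., None], axis=-1)
        return g4.reshape(N, C, H // 2, W // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


class Downsample2x(Layer):
    """Keep every second row/column.  A stride-1 convolution followed by this
    layer computes exactly a stride-2 convolution."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x[:, :, ::2, ::2]

    def backward(self, gy):
        gx = np.zeros(self._shape, dtype=gy.dtype)
        gx[:, :, ::2, ::2] = gy
        return gx


_UPSAMPLE_MATS: dict = {}


def _upsample_matrix(n_in: int) -> np.ndarray:
    """(2n, n) interpolation matrix for 2x bilinear upsampling with
    half-pixel-centered mapping and clamped edges."""
    if n_in not in _UPSAMPLE_MATS:
        src = np.clip((np.arange(2 * n_in) + 0.5) / 2.0 - 0.5, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = (src - i0).astype(DTYPE)
        m = np.zeros((2 * n_in, n_in), dtype=DTYPE)
        m[np.arange(2 * n_in), i0] += 1.0 - w1
        m[np.arange(2 * n_in), i1] += w1
        _UPSAMPLE_MATS[n_in] = m
    return _UPSAMPLE_MATS[n_in]


class UpsampleBilinear2x(Layer):
    """Fixed (parameter-free) bilinear 2x upsampling, realized as separable
    interpolation-matrix products; backward is the exact adjoint."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        H, W = x.shape[2], x.shape[3]
        mz, mx = _upsample_matrix(H), _upsample_matrix(W)
        y = np.einsum("is,ncsw->nciw", mz, x, optimize=True)
        return np.einsum("jw,nciw->ncij", mx, y, optimize=True)

    def backward(self, gy):
        H, W = self._in_shape[2], self._in_shape[3]
        mz, mx = _upsample_matrix(H), _upsample_matrix(W)
        g = np.einsum("jw,ncij->nciw", mx, gy, optimize=True)
        return np.einsum("is,nciw->ncsw", mz, g, optimize=True)


def upsample_bilinear2x(x: np.ndarray) -> np.ndarray:
    """Functional bilinear 2x upsampling of an (H, W) or (N, C, H, W) array."""
    if x.ndim == 2:
        return UpsampleBilinear2x().forward(x[None, None])[0, 0]
    return UpsampleBilinear2x().forward(x)


class GlobalMean(Layer):
    """Spatial + channel mean to a per-sample scalar (critic head)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, gy):
        N, C, H, W = self._shape
        return np.broadcast_to(gy[:, None, None, None] / (C * H * W),
                               self._shape).copy()


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


# --------------------------------------------------------------------------- #
# optimization
# --------------------------------------------------------------------------- #

class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_params(params, bound: float) -> None:
    """Clip every parameter tensor elementwise to [-bound, bound] (Wasserstein
    critic weight clipping)."""
    for p in params:
        np.clip(p.value, -bound, bound, out=p.value)
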