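"""Minimal NumPy neural-network layers with exact analytic gradients.

Feature maps are (N, C, H, W) arrays.  Each layer caches what its backward
pass needs during ``forward(training=True)`` and exposes ``params``/``grads``
dicts keyed by parameter name ("W"/"b" for convolutions, "gamma"/"beta" for
batch norm) so the optimizer can walk the whole network generically.
Convolutions use im2col + BLAS matmuls; the gradient of a stride-1
same-padded convolution with respect to its input is the same-padded
correlation of the output gradient with the spatially flipped, axis-swapped
kernel.  All gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d", "ConvTranspose2d", "MaxPool2x2", "ReLU", "Dropout", "BatchNorm2d",
]


class Layer:
    """Base: parameterless layers inherit empty params/grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix under same padding."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, _, _ = x.shape
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    h, w = win.shape[2], win.shape[3]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k), h, w


class Conv2d(Layer):
    """k x k stride-1 convolution with "same" zero padding (k odd)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.has_bias = bias
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.params["W"] = rng.normal(0.0, scale,
                                      (out_channels, in_channels, kernel, kernel)).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._x: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        if training:
            self._x = x
        return self._conv(x, self.params["W"], self.params.get("b"))

    def _conv(self, x, W, b):
        n = x.shape[0]
        cols, h, w = _im2col(x, self.kernel)
        out = cols @ W.reshape(W.shape[0], -1).T
        if b is not None:
            out += b
        return out.reshape(n, h, w, W.shape[0]).transpose(0, 3, 1, 2)

    def backward(self, dout):
        x = self._x
        n, _, h, w = x.shape
        cols, _, _ = _im2col(x, self.kernel)
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        if self.has_bias:
            self.grads["b"] = dmat.sum(axis=0)
        # dL/dx = same-conv of dout with flipped kernel, in/out axes swapped.
        W_hat = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_d, _, _ = _im2col(dout, self.kernel)
        dx = cols_d @ W_hat.reshape(self.in_channels, -1).T
        return dx.reshape(n, h, w, self.in_channels).transpose(0, 3, 1, 2)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution: each input pixel stamps a 2x2
    weighted block into a twice-sized output (learnable upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 2,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        if kernel != 2:
            raise ValueError("only 2x2 stride-2 transposed convolution is supported")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.has_bias = bias
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_channels)
        self.params["W"] = rng.normal(0.0, scale,
                                      (in_channels, out_channels, 2, 2)).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._x = None

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        n, _, h, w = x.shape
        y = np.einsum("nchw,coab->nohawb", x, self.params["W"], optimize=True)
        y = y.reshape(n, self.out_channels, 2 * h, 2 * w)
        if self.has_bias:
            y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dout):
        x = self._x
        n, _, h, w = x.shape
        d = dout.reshape(n, self.out_channels, h, 2, w, 2)
        self.grads["W"] = np.einsum("nchw,nohawb->coab", x, d, optimize=True)
        if self.has_bias:
            self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return np.einsum("nohawb,coab->nchw", d, self.params["W"], optimize=True)


class MaxPool2x2(Layer):
    """Non-overlapping 2x2 max pooling; halves each spatial dimension."""

    def __init__(self) -> None:
        super().__init__()
        self._idx = None
        self._shape = None

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._shape = (n, c, h, w)
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, self._idx[..., None], dout[..., None], axis=-1)
        dblocks = dblocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dblocks.reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float64):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return g * xhat + b

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * inv[None, :, None, None]
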