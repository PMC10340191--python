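"""Primitive layers: convolutions, batch norm, linear, activations, pooling.

All arrays are float32, NCHW.  Convolutions carry no bias by default because a
batch-norm follows them everywhere in the backbone.
"""

from __future__ import annotations

import numpy as np

from .functional import col2im, conv_out_size, im2col
from .module import Module, Parameter


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape, dtype=np.float32) * np.float32(
        np.sqrt(2.0 / fan_in)
    )


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=1, pad=None, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(
            he_normal(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self._cache = None

    def forward(self, x):
        cols, Ho, Wo = im2col(x, self.k, self.stride, self.pad)
        Wm = self.weight.data.reshape(self.out_ch, -1)
        y = np.matmul(Wm, cols)
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        self._cache = (cols, x.shape, Ho, Wo)
        return y.reshape(x.shape[0], self.out_ch, Ho, Wo)

    def backward(self, grad):
        cols, x_shape, Ho, Wo = self._cache
        B = x_shape[0]
        g = grad.reshape(B, self.out_ch, Ho * Wo)
        Wm = self.weight.data.reshape(self.out_ch, -1)
        self.weight.grad += np.einsum("bol,bkl->ok", g, cols).reshape(
            self.weight.data.shape
        )
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        gcols = np.matmul(Wm.T, g)
        return col2im(gcols, x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Stride-2 3x3 transposed convolution; doubles the spatial size exactly
    (padding 1, output padding 1), which makes upsampled maps line up with the
    target branch resolution without cropping."""

    def __init__(self, in_ch, out_ch, k=3, stride=2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        self.weight = Parameter(he_normal(rng, (in_ch, out_ch, k, k), in_ch))
        self._cache = None

    def forward(self, x):
        B, C, H, W = x.shape
        Hout, Wout = self.stride * H, self.stride * W
        x_flat = x.reshape(B, C, H * W)
        Wm = self.weight.data.reshape(self.in_ch, -1)  # (Cin, Cout*k*k)
        cols = np.matmul(Wm.T[None], x_flat)  # (B, Cout*k*k, H*W)
        y = col2im(cols, (B, self.out_ch, Hout, Wout), self.k, self.stride, self.pad)
        self._cache = (x_flat, (B, C, H, W))
        return y

    def backward(self, grad):
        x_flat, x_shape = self._cache
        B = x_shape[0]
        gcols, _, _ = im2col(grad, self.k, self.stride, self.pad)
        Wm = self.weight.data.reshape(self.in_ch, -1)
        self.weight.grad += np.einsum("bil,bkl->ik", x_flat, gcols).reshape(
            self.weight.data.shape
        )
        gx = np.matmul(Wm[None], gcols)
        return gx.reshape(x_shape)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self._cache = None

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, invstd = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        scale = (self.gamma.data * invstd)[None, :, None, None]
        if not self.training:
            return grad * scale
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g_mean = grad.mean(axis=(0, 2, 3))[None, :, None, None]
        gx_mean = (grad * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / n
        return scale * (grad - g_mean - xhat * gx_mean)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(he_normal(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f)) if bias else None
        self._cache = None

    def forward(self, x):
        self._cache = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, grad):
        x = self._cache
        self.weight.grad += grad.T @ x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, grad):
        return np.where(self._mask, grad, np.float32(0.0))


SIGMOID_EPS = np.float32(1e-7)  # keeps logistic outputs strictly inside (0,1)


def stable_sigmoid(x):
    y = 1.0 / (1.0 + np.exp(-x, dtype=np.float32))
    return np.clip(y, SIGMOID_EPS, 1.0 - SIGMOID_EPS)


class Sigmoid(Module):
    def forward(self, x):
        self._y = stable_sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class HardSwish(Module):
    """x * relu6(x + 3) / 6 — the delta nonlinearity of the attention transform."""

    def forward(self, x):
        self._x = x
        self._r = np.clip(x + 3.0, 0.0, 6.0).astype(np.float32)
        return x * self._r / np.float32(6.0)

    def backward(self, grad):
        inner = ((self._x > -3.0) & (self._x < 3.0)).astype(np.float32)
        return grad * (self._r / 6.0 + self._x * inner / 6.0)


class GlobalAvgPool(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / np.float32(H * W), self._shape
        ).copy()


__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "HardSwish",
    "GlobalAvgPool",
    "he_normal",
    "conv_out_size",
]
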