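"""Conditionally parameterized (dynamic) convolution.

The layer keeps a bank of ``n`` expert kernels W_1..W_n of standard shape and a
routing function r(x) = sigmoid(FC(GAP(x))) producing one mixture coefficient
alpha_i per expert and sample.  The effective kernel for a sample is the
aggregate sum_i alpha_i * W_i, so only one convolution's worth of work is done
per sample at runtime; by linearity this equals the alpha-weighted sum of the
per-expert convolutions, which is the identity the test suite checks.
"""

from __future__ import annotations

import numpy as np

from .functional import col2im, im2col
from .module import Module, Parameter
from .layers import he_normal, stable_sigmoid


class Routing(Module):
    """GAP -> single fully connected layer -> sigmoid, one output per expert."""

    def __init__(self, in_ch: int, num_experts: int, rng=None):
        super().__init__()
        if num_experts < 1:
            raise ValueError(f"num_experts must be >= 1, got {num_experts}")
        rng = rng or np.random.default_rng()
        self.in_ch, self.num_experts = in_ch, num_experts
        self.weight = Parameter(he_normal(rng, (num_experts, in_ch), in_ch))
        self.bias = Parameter(np.zeros(num_experts))
        self._cache = None

    def forward(self, x):
        pooled = x.mean(axis=(2, 3))
        logits = pooled @ self.weight.data.T + self.bias.data
        alphas = stable_sigmoid(logits)
        self._cache = (pooled, alphas, x.shape)
        return alphas

    def backward(self, g_alphas):
        pooled, alphas, x_shape = self._cache
        g_logits = g_alphas * alphas * (1.0 - alphas)
        self.weight.grad += g_logits.T @ pooled
        self.bias.grad += g_logits.sum(axis=0)
        g_pooled = g_logits @ self.weight.data
        B, C, H, W = x_shape
        return np.broadcast_to(
            g_pooled[:, :, None, None] / np.float32(H * W), x_shape
        ).copy()


class CondConv2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=1, pad=None, num_experts=3,
                 bias=False, rng=None):
        super().__init__()
        if num_experts < 1:
            raise ValueError(f"num_experts must be >= 1, got {num_experts}")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2 if pad is None else pad
        self.num_experts = num_experts
        self.experts = Parameter(
            he_normal(rng, (num_experts, out_ch, in_ch, k, k), in_ch * k * k)
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.routing = Routing(in_ch, num_experts, rng=rng)
        self._cache = None

    def routing_weights(self, x) -> np.ndarray:
        """Per-sample mixture coefficients alpha in (0,1), shape (B, n)."""
        return self.routing.forward(x)

    def forward(self, x, alphas=None):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        if alphas is None:
            alphas = self.routing.forward(x)
            routed = True
        else:
            routed = False
        if alphas.shape[0] != x.shape[0]:
            raise ValueError(
                f"routing batch {alphas.shape[0]} != input batch {x.shape[0]}"
            )
        B = x.shape[0]
        cols, Ho, Wo = im2col(x, self.k, self.stride, self.pad)
        bank = self.experts.data.reshape(self.num_experts, self.out_ch, -1)
        wmix = np.einsum("bn,nok->bok", alphas, bank)  # per-sample kernel
        y = np.matmul(wmix, cols)
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        self._cache = (cols, alphas, wmix, x.shape, Ho, Wo, routed)
        return y.reshape(B, self.out_ch, Ho, Wo)

    def backward(self, grad):
        cols, alphas, wmix, x_shape, Ho, Wo, routed = self._cache
        B = x_shape[0]
        g = grad.reshape(B, self.out_ch, Ho * Wo)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        g_wmix = np.matmul(g, cols.transpose(0, 2, 1))  # (B, O, C*k*k)
        bank = self.experts.data.reshape(self.num_experts, self.out_ch, -1)
        self.experts.grad += np.einsum("bn,bok->nok", alphas, g_wmix).reshape(
            self.experts.data.shape
        )
        gcols = np.matmul(wmix.transpose(0, 2, 1), g)
        gx = col2im(gcols, x_shape, self.k, self.stride, self.pad)
        if routed:
            g_alphas = np.einsum("bok,nok->bn", g_wmix, bank)
            gx += self.routing.backward(g_alphas)
        return gx
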