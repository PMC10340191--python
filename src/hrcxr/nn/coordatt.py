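"""Coordinate attention.

Features are pooled along each spatial direction separately (row means and
column means per channel), passed through a shared 1x1 transform with batch
norm and hard-swish, then split into two directional 1x1 convolutions whose
sigmoid outputs gate the input multiplicatively:

    y[c,i,j] = x[c,i,j] * g_h[c,i] * g_w[c,j]

Both gates lie strictly in (0,1), so the block can only attenuate; the two
factors jointly encode channel importance and spatial position.
"""

from __future__ import annotations

import warnings

import numpy as np

from .layers import BatchNorm2d, HardSwish, he_normal, stable_sigmoid
from .module import Module, Parameter


def directional_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-channel row means (B,C,H,1) and column means (B,C,1,W)."""
    if x.ndim != 4 or x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError(f"expected 4-axis feature map with H,W >= 1, got {x.shape}")
    z_h = x.mean(axis=3, keepdims=True)
    z_w = x.mean(axis=2, keepdims=True)
    return z_h, z_w


def reweight(x: np.ndarray, g_h: np.ndarray, g_w: np.ndarray) -> np.ndarray:
    """Gate features: broadcasts g_h over width and g_w over height."""
    if g_h.shape[1] != x.shape[1] or g_w.shape[1] != x.shape[1]:
        raise ValueError("attention maps must match the input channel count")
    return x * g_h * g_w


class CoordinateAttention(Module):
    def __init__(self, ch: int, reduction: int = 32, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.ch = ch
        if ch % reduction != 0:
            warnings.warn(
                f"channel count {ch} not divisible by reduction {reduction}; "
                "using floor division (minimum 1)"
            )
        self.mid = max(1, ch // reduction)
        self.w_shared = Parameter(he_normal(rng, (self.mid, ch), ch))
        self.bn = BatchNorm2d(self.mid)
        self.act = HardSwish()
        self.w_h = Parameter(he_normal(rng, (ch, self.mid), self.mid))
        self.b_h = Parameter(np.zeros(ch))
        self.w_w = Parameter(he_normal(rng, (ch, self.mid), self.mid))
        self.b_w = Parameter(np.zeros(ch))
        self._cache = None

    # -- pieces ------------------------------------------------------------
    def attention_maps(self, z_h, z_w):
        """(B,C,H,1),(B,C,1,W) summaries -> gates g_h (B,C,H,1), g_w (B,C,1,W)."""
        B, C, H, _ = z_h.shape
        W = z_w.shape[3]
        z = np.concatenate([z_h[:, :, :, 0], z_w[:, :, 0, :]], axis=2)  # (B,C,H+W)
        f = np.einsum("mc,bcl->bml", self.w_shared.data, z)
        f = self.act.forward(self.bn.forward(f[:, :, :, None]))[:, :, :, 0]
        f_h, f_w = f[:, :, :H], f[:, :, H:]
        a_h = np.einsum("cm,bml->bcl", self.w_h.data, f_h) + self.b_h.data[None, :, None]
        a_w = np.einsum("cm,bml->bcl", self.w_w.data, f_w) + self.b_w.data[None, :, None]
        g_h = stable_sigmoid(a_h)
        g_w = stable_sigmoid(a_w)
        self._att_cache = (z, f_h, f_w, g_h, g_w, H, W)
        return g_h[:, :, :, None], g_w[:, :, None, :]

    # -- module interface ---------------------------------------------------
    def forward(self, x):
        z_h, z_w = directional_pool(x)
        g_h, g_w = self.attention_maps(z_h, z_w)
        self._cache = (x, g_h, g_w)
        return reweight(x, g_h, g_w)

    def backward(self, grad):
        x, g_h, g_w = self._cache
        z, f_h, f_w, gh_flat, gw_flat, H, W = self._att_cache
        gx = grad * g_h * g_w
        g_gh = (grad * x * g_w).sum(axis=3)          # (B,C,H)
        g_gw = (grad * x * g_h).sum(axis=2)          # (B,C,W)
        # through the sigmoids
        g_ah = g_gh * gh_flat * (1.0 - gh_flat)
        g_aw = g_gw * gw_flat * (1.0 - gw_flat)
        # directional 1x1 convs
        self.w_h.grad += np.einsum("bcl,bml->cm", g_ah, f_h)
        self.b_h.grad += g_ah.sum(axis=(0, 2))
        self.w_w.grad += np.einsum("bcl,bml->cm", g_aw, f_w)
        self.b_w.grad += g_aw.sum(axis=(0, 2))
        g_fh = np.einsum("cm,bcl->bml", self.w_h.data, g_ah)
        g_fw = np.einsum("cm,bcl->bml", self.w_w.data, g_aw)
        g_f = np.concatenate([g_fh, g_fw], axis=2)[:, :, :, None]
        g_pre = self.bn.backward(self.act.backward(g_f))[:, :, :, 0]
        self.w_shared.grad += np.einsum("bml,bcl->mc", g_pre, z)
        g_z = np.einsum("mc,bml->bcl", self.w_shared.data, g_pre)
        # split back to the two pooling branches and undo the means
        g_zh, g_zw = g_z[:, :, :H], g_z[:, :, H:]
        gx += g_zh[:, :, :, None] / np.float32(W)
        gx += g_zw[:, :, None, :] / np.float32(H)
        return gx
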