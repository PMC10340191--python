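"""im2col/col2im patch extraction used by every convolution layer."""

from __future__ import annotations

import numpy as np


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold ``x`` (B,C,H,W) into patch columns (B, C*k*k, Ho*Wo)."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = conv_out_size(H, k, stride, pad)
    Wo = conv_out_size(W, k, stride, pad)
    sB, sC, sH, sW = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, k, k, Ho, Wo),
        strides=(sB, sC, sH, sW, stride * sH, stride * sW),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(B, C * k * k, Ho * Wo)
    return cols, Ho, Wo


def col2im(
    cols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Scatter-add patch columns back onto an image; adjoint of :func:`im2col`."""
    B, C, H, W = x_shape
    Ho = conv_out_size(H, k, stride, pad)
    Wo = conv_out_size(W, k, stride, pad)
    cols = cols.reshape(B, C, k, k, Ho, Wo)
    out = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        i_end = i + stride * Ho
        for j in range(k):
            j_end = j + stride * Wo
            out[:, :, i:i_end:stride, j:j_end:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out
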