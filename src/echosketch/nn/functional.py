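"""Low-level convolution primitives (forward / input-grad / weight-grad).

All three views of the same bilinear map are implemented once, im2col style,
and the transposed convolution reuses them: its forward IS the input-gradient
of the corresponding convolution, and vice versa.

Tensor layout is (N, C, H, W) throughout, float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_out_size",
    "conv_forward",
    "conv_input_grad",
    "conv_weight_grad",
]


def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def _im2col(x: np.ndarray, kernel: int, stride: int, padding: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C, k, k) patch view (copy after padding)."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(x, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv_forward(
    x: np.ndarray, w: np.ndarray, stride: int, padding: int
) -> np.ndarray:
    """Cross-correlation of x (N,Ci,H,W) with w (Co,Ci,k,k) -> (N,Co,Ho,Wo)."""
    n = x.shape[0]
    co, ci, k, _ = w.shape
    col = _im2col(x, k, stride, padding)  # (N, Ho, Wo, Ci, k, k)
    ho, wo = col.shape[1], col.shape[2]
    y = col.reshape(n * ho * wo, ci * k * k) @ w.reshape(co, -1).T
    return y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)


def conv_input_grad(
    dy: np.ndarray,
    w: np.ndarray,
    stride: int,
    padding: int,
    input_hw: tuple[int, int],
) -> np.ndarray:
    """Gradient w.r.t. x of conv_forward, i.e. the transposed convolution.

    dy: (N, Co, Ho, Wo); returns (N, Ci, H, W) with (H, W) = input_hw.
    """
    n, co, ho, wo = dy.shape
    _, ci, k, _ = w.shape
    h, wdt = input_hw
    dcol = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, co) @ w.reshape(co, -1)
    dcol = dcol.reshape(n, ho, wo, ci, k, k).transpose(0, 3, 4, 5, 1, 2)
    # dcol: (N, Ci, k, k, Ho, Wo); scatter-add into the padded input frame.
    dxp = np.zeros((n, ci, h + 2 * padding, wdt + 2 * padding))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                dcol[:, :, i, j]
            )
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv_weight_grad(
    x: np.ndarray, dy: np.ndarray, kernel: int, stride: int, padding: int
) -> np.ndarray:
    """Gradient w.r.t. w of conv_forward. x: (N,Ci,H,W), dy: (N,Co,Ho,Wo)."""
    n, co, ho, wo = dy.shape
    ci = x.shape[1]
    col = _im2col(x, kernel, stride, padding).reshape(n * ho * wo, -1)
    dw = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, co).T @ col
    return dw.reshape(co, ci, kernel, kernel)
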