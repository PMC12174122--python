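"""im2col/col2im primitives shared by the convolution and pooling layers."""

from __future__ import annotations

import numpy as np


def conv_out_size(size: int, kernel: int, stride: int, pad: int, dilation: int) -> int:
    eff = dilation * (kernel - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
           dilation: int) -> np.ndarray:
    """Unfold ``x`` [N,C,H,W] into patches [N,C,kh,kw,Ho,Wo]."""
    n, c, h, w = x.shape
    ho = conv_out_size(h, kh, stride, pad, dilation)
    wo = conv_out_size(w, kw, stride, pad, dilation)
    if ho <= 0 or wo <= 0:
        raise ValueError(f"kernel {kh}x{kw} (dilation {dilation}) does not fit "
                         f"input {h}x{w} with pad {pad}")
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :,
                                 i * dilation: i * dilation + stride * ho: stride,
                                 j * dilation: j * dilation + stride * wo: stride]
    return cols


def col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int,
           pad: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add of patch gradients)."""
    n, c, h, w = x_shape
    ho, wo = cols.shape[-2:]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :,
               i * dilation: i * dilation + stride * ho: stride,
               j * dilation: j * dilation + stride * wo: stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:pad + h, pad:pad + w]
    return xp
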