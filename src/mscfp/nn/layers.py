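"""Convolution, normalization, activation, pooling and linear layers.

All layers operate on [N, C, H, W] arrays (Linear on [N, F]) and implement
the forward/backward contract of :class:`~mscfp.nn.core.Module`.
Convolution supports stride, zero padding, dilation and channel groups via
im2col + GEMM, which is what grouped ResNeXt branches and dilated context
branches both need.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Param
from .functional import col2im, conv_out_size, im2col


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with groups and dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("in/out channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        self.weight = Param(_he_init(rng, (out_channels, in_channels // groups, k, k),
                                     fan_in, dtype), "weight")
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected [N,{self.in_channels},H,W], got {x.shape}")
        n = x.shape[0]
        k, g = self.kernel_size, self.groups
        cols = im2col(x, k, k, self.stride, self.padding, self.dilation)
        ho, wo = cols.shape[-2:]
        # [g, Cout/g, K] @ [N, g, K, L] -> [N, g, Cout/g, L], K = (C/g)*k*k
        cols_g = cols.reshape(n, g, (self.in_channels // g) * k * k, ho * wo)
        w_g = self.weight.data.reshape(g, self.out_channels // g, -1)
        out = np.matmul(w_g[None], cols_g)
        out = out.reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (x.shape, cols_g)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols_g = self._cache
        n = grad.shape[0]
        k, g = self.kernel_size, self.groups
        ho, wo = grad.shape[-2:]
        g_out = np.ascontiguousarray(
            grad.reshape(n, g, self.out_channels // g, ho * wo))
        w_g = self.weight.data.reshape(g, self.out_channels // g, -1)
        # merge batch into the contraction: [g,O,N*L] @ [g,N*L,K] -> [g,O,K]
        go_m = np.ascontiguousarray(g_out.transpose(1, 2, 0, 3)).reshape(
            g, self.out_channels // g, n * ho * wo)
        cl_m = np.ascontiguousarray(cols_g.transpose(1, 0, 3, 2)).reshape(
            g, n * ho * wo, -1)
        dw = np.matmul(go_m, cl_m)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dcols = np.matmul(w_g.transpose(0, 2, 1)[None], g_out)
        dcols = dcols.reshape(n, self.in_channels, k, k, ho, wo)
        return col2im(dcols, x_shape, k, k, self.stride, self.padding, self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(num_features, dtype=dtype), "gamma")
        self.beta = Param(np.zeros(num_features, dtype=dtype), "beta")
        self._buf_running_mean = np.zeros(num_features, dtype=dtype)
        self._buf_running_var = np.ones(num_features, dtype=dtype)
        self._cache = None

    def _cast_buffers(self, dtype):
        self._buf_running_mean = self._buf_running_mean.astype(dtype)
        self._buf_running_var = self._buf_running_var.astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.num_features:
            raise ValueError(f"expected {self.num_features} channels, got {x.shape[1]}")
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self._buf_running_mean = (1 - m) * self._buf_running_mean + m * mean
            self._buf_running_var = (1 - m) * self._buf_running_var + m * var
        else:
            mean = self._buf_running_mean
            var = self._buf_running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * inv_std[None, :, None, None]
        # train mode: mean/var depend on the batch
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g_mean = g.mean(axis=axes)[None, :, None, None]
        gx_mean = (g * xhat).mean(axis=axes)[None, :, None, None]
        del m
        return inv_std[None, :, None, None] * (g - g_mean - xhat * gx_mean)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x):
        out = np.empty_like(x)
        np.negative(np.abs(x), out=out)
        np.exp(out, out=out)           # e^{-|x|}, never overflows
        pos = x >= 0
        out = np.where(pos, 1.0 / (1.0 + out), out / (1.0 + out))
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class HardSwish(Module):
    """x * relu6(x + 3) / 6 — the nonlinearity used in the attention stem."""

    def __init__(self):
        super().__init__()
        self._x = None

    def forward(self, x):
        self._x = x
        return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        x = self._x
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return grad * d


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x):
        k = self.kernel_size
        if self.padding:
            # pad with -inf so padded cells never win the max
            neg = np.finfo(x.dtype).min
            xp = np.pad(x, ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2),
                        constant_values=neg)
        else:
            xp = x
        cols = im2col(xp, k, k, self.stride, 0, 1)
        n, c, _, _, ho, wo = cols.shape
        cols = cols.reshape(n, c, k * k, ho, wo)
        idx = cols.argmax(axis=2)
        out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (x.shape, xp.shape, idx)
        return out

    def backward(self, grad):
        x_shape, xp_shape, idx = self._cache
        k = self.kernel_size
        n, c, ho, wo = grad.shape
        dcols = np.zeros((n, c, k * k, ho, wo), dtype=grad.dtype)
        np.put_along_axis(dcols, idx[:, :, None], grad[:, :, None], axis=2)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = col2im(dcols, xp_shape, k, k, self.stride, 0, 1)
        if self.padding:
            p = self.padding
            return dxp[:, :, p:p + x_shape[2], p:p + x_shape[3]]
        return dxp


class GlobalAvgPool(Module):
    """[N, C, H, W] -> [N, C] spatial mean."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.weight = Param((rng.uniform(-scale, scale,
                                         (out_features, in_features))).astype(dtype),
                            "weight")
        self.bias = Param(np.zeros(out_features, dtype=dtype), "bias") if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


def upsample_nearest(x: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize to ``target_hw`` (used top-down in the pyramid)."""
    ht, wt = target_hw
    h, w = x.shape[-2:]
    idx_h = (np.arange(ht) * h) // ht
    idx_w = (np.arange(wt) * w) // wt
    return x[:, :, idx_h][:, :, :, idx_w]


def upsample_nearest_backward(grad: np.ndarray, src_hw: tuple[int, int]) -> np.ndarray:
    h, w = src_hw
    n, c, ht, wt = grad.shape
    idx_h = (np.arange(ht) * h) // ht
    idx_w = (np.arange(wt) * w) // wt
    tmp = np.zeros((n, c, h, wt), dtype=grad.dtype)
    np.add.at(tmp, (slice(None), slice(None), idx_h), grad)
    out = np.zeros((n, c, h, w), dtype=grad.dtype)
    np.add.at(out, (slice(None), slice(None), slice(None), idx_w), tmp)
    return out
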