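"""Coordinate attention: direction-wise pooling, joint transform, gating.

The input map is average-pooled along the width (giving a C x H code) and
along the height (C x W), the two codes are concatenated on the spatial
axis and passed through a shared 1x1 convolution to C/r channels with
batch norm and hard-swish, then split back and expanded per direction to C
channels with a sigmoid, yielding gates m_h in (0,1)^{C x H x 1} and
m_w in (0,1)^{C x 1 x W} that multiply the input.  The reduction r trades
capacity for cost; the reduced width is floored at 8 channels.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, HardSwish, Module, Sigmoid


def directional_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-direction global average pools.

    ``y_h[n,c,h]`` is the mean of row h over the width; ``y_w[n,c,w]`` is
    the mean of column w over the height.  Accepts [C,H,W] or [N,C,H,W].
    """
    x = np.asarray(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected [C,H,W] or [N,C,H,W]")
    y_h = x.mean(axis=3)
    y_w = x.mean(axis=2)
    if squeeze:
        return y_h[0], y_w[0]
    return y_h, y_w


class CoordAttention(Module):
    def __init__(self, channels: int, reduction: int = 32,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        reduced = max(8, channels // reduction)
        self.reduced = reduced
        self.conv_joint = Conv2d(channels, reduced, 1, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(reduced, dtype=dtype)
        self.act = HardSwish()
        self.conv_h = Conv2d(reduced, channels, 1, rng=rng, dtype=dtype)
        self.conv_w = Conv2d(reduced, channels, 1, rng=rng, dtype=dtype)
        self.sig_h = Sigmoid()
        self.sig_w = Sigmoid()
        self._cache = None

    def attention_maps(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Forward up to the gates; returns (m_h [N,C,H,1], m_w [N,C,1,W])."""
        n, c, h, w = x.shape
        y_h = x.mean(axis=3)                       # [N,C,H]
        y_w = x.mean(axis=2)                       # [N,C,W]
        joint = np.concatenate([y_h, y_w], axis=2)[:, :, :, None]  # [N,C,H+W,1]
        f = self.act(self.bn(self.conv_joint(joint)))
        f_h, f_w = f[:, :, :h], f[:, :, h:]
        m_h = self.sig_h(self.conv_h(f_h))          # [N,C,H,1]
        m_w_col = self.sig_w(self.conv_w(f_w))      # [N,C,W,1]
        m_w = m_w_col.transpose(0, 1, 3, 2)         # [N,C,1,W]
        self._cache = (x, m_h, m_w, h, w)
        return m_h, m_w

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        m_h, m_w = self.attention_maps(x)
        return x * m_h * m_w

    def backward(self, grad):
        x, m_h, m_w, h, w = self._cache
        dx = grad * m_h * m_w
        dm_h = (grad * x * m_w).sum(axis=3, keepdims=True)        # [N,C,H,1]
        dm_w = (grad * x * m_h).sum(axis=2, keepdims=True)        # [N,C,1,W]
        df_h = self.conv_h.backward(self.sig_h.backward(dm_h))
        df_w = self.conv_w.backward(self.sig_w.backward(
            dm_w.transpose(0, 1, 3, 2)))
        df = np.concatenate([df_h, df_w], axis=2)
        djoint = self.conv_joint.backward(self.bn.backward(self.act.backward(df)))
        dy_h = djoint[:, :, :h, 0]                 # [N,C,H]
        dy_w = djoint[:, :, h:, 0]                 # [N,C,W]
        dx += dy_h[:, :, :, None] / w              # pooling adjoints
        dx += dy_w[:, :, None, :] / h
        return dx
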