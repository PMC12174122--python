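"""Bidirectional feature-pyramid fusion over the five backbone stage outputs.

All five stage maps are first harmonized to a common channel width with
1x1 convolutions.  One Bi-FPN layer then runs a top-down pass (each level
fuses its input with the x2-upsampled deeper node) followed by a bottom-up
pass (each level fuses its input, its top-down node and the downsampled
shallower output).  Every fusion node carries nonnegative learned weights
normalized as w_i / (sum_j w_j + eps) — "fast normalized fusion" — so each
node output is a convex combination of its resized inputs.  A global
average pool and a fully connected layer on one pyramid level produce the
4-class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d,
                 Module, Param, ReLU, Sequential, upsample_nearest,
                 upsample_nearest_backward)

FUSION_EPS = 1e-4


@dataclass
class PyramidFeatures:
    """Equal-width feature maps at strictly decreasing resolution."""

    levels: list
    width: int

    def __post_init__(self):
        for a, b in zip(self.levels, self.levels[1:]):
            if a.shape[2] <= b.shape[2] or a.shape[3] <= b.shape[3]:
                raise ValueError("pyramid levels must strictly decrease "
                                 "in resolution")
        for lv in self.levels:
            if lv.shape[1] != self.width:
                raise ValueError("all pyramid levels must share the same width")

    def __len__(self):
        return len(self.levels)


class Harmonize(Module):
    """1x1 conv + batch norm mapping each stage output to a common width."""

    def __init__(self, in_channels: list[int], width: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.width = width
        self.projs = [Sequential(Conv2d(c, width, 1, rng=rng, dtype=dtype),
                                 BatchNorm2d(width, dtype=dtype))
                      for c in in_channels]

    def forward(self, stage_outputs: list[np.ndarray]) -> PyramidFeatures:
        if len(stage_outputs) != len(self.projs):
            raise ValueError(f"expected {len(self.projs)} stage outputs, "
                             f"got {len(stage_outputs)}")
        levels = [p(x) for p, x in zip(self.projs, stage_outputs)]
        return PyramidFeatures(levels=levels, width=self.width)

    def backward(self, dlevels: list[np.ndarray]) -> list[np.ndarray]:
        return [p.backward(g) for p, g in zip(self.projs, dlevels)]


class FusionNode(Module):
    """Fast-normalized weighted fusion of same-shaped inputs + optional conv."""

    def __init__(self, n_inputs: int, width: int, post_conv: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fusion_raw = Param(np.ones(n_inputs, dtype=dtype), "fusion_raw")
        # depthwise-separable conv after fusion, as in the original Bi-FPN
        self.post = Sequential(Conv2d(width, width, 3, padding=1, groups=width,
                                      rng=rng, dtype=dtype),
                               Conv2d(width, width, 1, rng=rng, dtype=dtype),
                               BatchNorm2d(width, dtype=dtype),
                               ReLU()) if post_conv else None
        self._cache = None

    def normalized_weights(self) -> np.ndarray:
        u = np.maximum(self.fusion_raw.data, 0.0)
        return u / (u.sum() + FUSION_EPS)

    def forward(self, inputs: list[np.ndarray]) -> np.ndarray:
        if len(inputs) != self.fusion_raw.size:
            raise ValueError("wrong number of fusion inputs")
        shape = inputs[0].shape
        for x in inputs[1:]:
            if x.shape != shape:
                raise ValueError(f"resolution mismatch between fused nodes: "
                                 f"{x.shape} vs {shape}")
        w = self.normalized_weights()
        fused = sum(wi * x for wi, x in zip(w, inputs))
        self._cache = (inputs, w)
        return self.post(fused) if self.post is not None else fused

    def backward(self, grad: np.ndarray) -> list[np.ndarray]:
        inputs, w = self._cache
        dfused = self.post.backward(grad) if self.post is not None else grad
        dinputs = [wi * dfused for wi in w]
        dw = np.array([float((dfused * x).sum()) for x in inputs])
        u = np.maximum(self.fusion_raw.data, 0.0)
        s = u.sum() + FUSION_EPS
        du = (dw - float(w @ dw)) / s
        self.fusion_raw.grad += np.where(self.fusion_raw.data > 0, du, 0.0) \
            .astype(self.fusion_raw.data.dtype)
        return dinputs


class BiFpnLayer(Module):
    """One top-down + bottom-up pass over a five-level pyramid."""

    def __init__(self, width: int, n_levels: int = 5, post_conv: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_levels = n_levels
        # top-down nodes for levels n-2 .. 0 (two inputs: own + upsampled)
        self.td_nodes = [FusionNode(2, width, post_conv, rng=rng, dtype=dtype)
                         for _ in range(n_levels - 1)]
        # bottom-up output nodes for levels 1 .. n-1; the deepest has no
        # separate top-down node, so it fuses two inputs instead of three
        self.out_nodes = [FusionNode(3 if i < n_levels - 1 else 2, width,
                                     post_conv, rng=rng, dtype=dtype)
                          for i in range(1, n_levels)]
        self.down_pools = [MaxPool2d(3, stride=2, padding=1)
                           for _ in range(n_levels - 1)]
        self._cache = None

    def forward(self, p: PyramidFeatures) -> PyramidFeatures:
        if len(p) != self.n_levels:
            raise ValueError(f"expected {self.n_levels} levels, got {len(p)}")
        levels = p.levels
        n = self.n_levels
        td = [None] * n
        td[n - 1] = levels[n - 1]
        for i in range(n - 2, -1, -1):
            up = upsample_nearest(td[i + 1], levels[i].shape[2:])
            td[i] = self.td_nodes[i].forward([levels[i], up])
        out = [None] * n
        out[0] = td[0]
        for i in range(1, n):
            down = self.down_pools[i - 1].forward(out[i - 1])
            if down.shape[2:] != levels[i].shape[2:]:
                raise ValueError(f"resolution mismatch between fused nodes: "
                                 f"{down.shape[2:]} vs {levels[i].shape[2:]}")
            inputs = [levels[i], td[i], down] if i < n - 1 else [levels[i], down]
            out[i] = self.out_nodes[i - 1].forward(inputs)
        self._cache = [t.shape for t in td]
        return PyramidFeatures(levels=out, width=p.width)

    def backward(self, dout: list[np.ndarray]) -> list[np.ndarray]:
        n = self.n_levels
        td_shapes = self._cache
        d_levels = [None] * n
        d_td = [None] * n
        d_out = [g.copy() for g in dout]

        def add(acc, g):
            return g if acc is None else acc + g

        for i in range(n - 1, 0, -1):
            dins = self.out_nodes[i - 1].backward(d_out[i])
            if i < n - 1:
                dlv, dtd, ddown = dins
                d_td[i] = add(d_td[i], dtd)
            else:
                dlv, ddown = dins
            d_levels[i] = add(d_levels[i], dlv)
            d_out[i - 1] = d_out[i - 1] + self.down_pools[i - 1].backward(ddown)
        d_td[0] = add(d_td[0], d_out[0])
        for i in range(0, n - 1):
            dlv, dup = self.td_nodes[i].backward(d_td[i])
            d_levels[i] = add(d_levels[i], dlv)
            d_td[i + 1] = add(d_td[i + 1], upsample_nearest_backward(
                dup, td_shapes[i + 1][2:]))
        d_levels[n - 1] = add(d_levels[n - 1], d_td[n - 1])
        return d_levels


class ClassifierHead(Module):
    """Global average pooling + fully connected layer on one pyramid level."""

    def __init__(self, width: int, n_classes: int = 4,
                 head_level: str = "deepest",
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        if head_level not in ("deepest", "highest"):
            raise ValueError("head_level must be 'deepest' or 'highest'")
        self.head_level = head_level
        self.gap = GlobalAvgPool()
        self.fc = Linear(width, n_classes, rng=rng, dtype=dtype)
        self._n_levels = None

    def level_index(self, n_levels: int) -> int:
        return n_levels - 1 if self.head_level == "deepest" else 0

    def forward(self, p: PyramidFeatures) -> np.ndarray:
        self._n_levels = len(p)
        x = p.levels[self.level_index(len(p))]
        return self.fc(self.gap(x))

    def forward_map(self, x: np.ndarray) -> np.ndarray:
        """Head applied directly to a single feature map (no-pyramid path)."""
        self._n_levels = None
        return self.fc(self.gap(x))

    def backward(self, dlogits: np.ndarray):
        dmap = self.gap.backward(self.fc.backward(dlogits))
        if self._n_levels is None:
            return dmap
        dlevels = [None] * self._n_levels
        dlevels[self.level_index(self._n_levels)] = dmap
        return dlevels


def classify(p: PyramidFeatures, head: ClassifierHead) -> np.ndarray:
    """Logits [N, n_classes] from a pyramid through the given head."""
    return head.forward(p)
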