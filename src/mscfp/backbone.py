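"""ResNeXt backbone: grouped-convolution bottleneck blocks in four stages.

Each block compresses its input with a 1x1 convolution into ``cardinality``
groups of ``bottleneck_width`` channels, applies a 3x3 grouped convolution
(equivalent to the 32 parallel branches summed position-wise), expands back
with a 1x1 convolution, and adds the (possibly projected) shortcut.  The
default stage plan is the canonical 32x4d layout with depths [3, 4, 6, 3]
and output widths 256/512/1024/2048 over a 64-channel stem; depths and
widths are configurable so tests can run scaled-down variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm2d, Conv2d, MaxPool2d, Module, ReLU, Sequential


@dataclass
class BlockSpec:
    in_channels: int
    out_channels: int
    bottleneck_width: int = 4
    cardinality: int = 32
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.bottleneck_width < 1 or self.cardinality < 1:
            raise ValueError("cardinality and bottleneck width must be >= 1")

    @property
    def mid_channels(self) -> int:
        return self.cardinality * self.bottleneck_width


class ResNeXtBlock(Module):
    """Bottleneck block: 1x1 compress -> 3x3 grouped -> 1x1 expand + shortcut."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = spec.mid_channels
        self.spec = spec
        self.conv1 = Conv2d(spec.in_channels, mid, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(mid, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid, mid, 3, stride=spec.stride, padding=1,
                            groups=spec.cardinality, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(mid, dtype=dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid, spec.out_channels, 1, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(spec.out_channels, dtype=dtype)
        self.relu_out = ReLU()
        if spec.stride != 1 or spec.in_channels != spec.out_channels:
            self.shortcut = Sequential(
                Conv2d(spec.in_channels, spec.out_channels, 1,
                       stride=spec.stride, rng=rng, dtype=dtype),
                BatchNorm2d(spec.out_channels, dtype=dtype))
        else:
            self.shortcut = None

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} channels, "
                             f"got {x.shape[1]}")
        h = self.relu1(self.bn1(self.conv1(x)))
        h = self.relu2(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        s = x if self.shortcut is None else self.shortcut(x)
        return self.relu_out(h + s)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(grad))))))))
        ds = grad if self.shortcut is None else self.shortcut.backward(grad)
        return dh + ds


DEFAULT_DEPTHS = (3, 4, 6, 3)
DEFAULT_WIDTHS = (64, 256, 512, 1024, 2048)


@dataclass
class BackboneConfig:
    depths: tuple = DEFAULT_DEPTHS
    widths: tuple = DEFAULT_WIDTHS          # stem width + 4 stage widths
    cardinality: int = 32
    bottleneck_width: int = 4               # per-group width in stage 1; x2/stage
    in_channels: int = 1                    # THz slices are single-channel

    def __post_init__(self):
        if len(self.widths) != len(self.depths) + 1:
            raise ValueError("widths must list the stem plus one width per stage")


class ResNeXtBackbone(Module):
    """Stem + four residual stages, exposing all five per-stage feature maps."""

    def __init__(self, cfg: BackboneConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        cfg = cfg or BackboneConfig()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        stem_w = cfg.widths[0]
        self.stem = Sequential(
            Conv2d(cfg.in_channels, stem_w, 7, stride=2, padding=3,
                   rng=rng, dtype=dtype),
            BatchNorm2d(stem_w, dtype=dtype),
            ReLU())
        self.pool = MaxPool2d(3, stride=2, padding=1)
        stages = []
        in_ch = stem_w
        for s, (depth, out_ch) in enumerate(zip(cfg.depths, cfg.widths[1:])):
            blocks = []
            bw = cfg.bottleneck_width * (2 ** s)
            for b in range(depth):
                spec = BlockSpec(in_channels=in_ch, out_channels=out_ch,
                                 bottleneck_width=bw, cardinality=cfg.cardinality,
                                 stride=2 if (b == 0 and s > 0) else 1)
                blocks.append(ResNeXtBlock(spec, rng=rng, dtype=dtype))
                in_ch = out_ch
            stages.append(Sequential(*blocks))
        self.stages = stages
        self.out_channels = list(cfg.widths)

    # -- plain-backbone interface (no context/attention inserts) ---------
    def forward_features(self, x) -> list[np.ndarray]:
        """[stem, stage1..stage4] maps; resolution halves at each element."""
        min_size = 2 * 2 ** len(self.stages)     # stem+pool then stride-2 stages
        if min(x.shape[2], x.shape[3]) < min_size:
            raise ValueError(f"input {x.shape[2]}x{x.shape[3]} smaller than the "
                             f"total downsampling factor {min_size}")
        feats = [self.stem(x)]
        h = self.pool(feats[0])
        for stage in self.stages:
            h = stage(h)
            feats.append(h)
        return feats

    def backward_features(self, dfeats: list[np.ndarray]) -> np.ndarray:
        """Adjoint of :meth:`forward_features` for a gradient per feature map."""
        grad = dfeats[-1]
        for i in range(len(self.stages) - 1, -1, -1):
            grad = self.stages[i].backward(grad)
            if i > 0:
                grad = grad + dfeats[i]
        grad = self.pool.backward(grad)
        return self.stem.backward(grad + dfeats[0])

    def forward(self, x):
        return self.forward_features(x)[-1]

    def backward(self, grad):
        raise NotImplementedError("use forward_features/backward_features")
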