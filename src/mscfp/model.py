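"""MSCFP-Net assembly: backbone + context + attention + pyramid + head.

The input image passes through the ResNeXt stem and four residual stages;
after each stage a multi-scale context module and a coordinate-attention
module refine the stage output (when enabled).  The five per-stage maps
feed the Bi-FPN, whose output pyramid is classified by a GAP + FC head.
With all three toggles off the model reduces exactly to the plain
backbone with the same head — the ablation baseline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .backbone import BackboneConfig, ResNeXtBackbone
from .bifpn import BiFpnLayer, ClassifierHead, Harmonize
from .coord_attention import CoordAttention
from .mcfem import Mcfem
from .nn import Module


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    mcfem_enabled: bool = True
    mcfem_dilations: tuple = (1, 2, 3, 4)
    ca_enabled: bool = True
    ca_reduction: int = 32
    bifpn_enabled: bool = True
    bifpn_width: int = 160
    bifpn_layers: int = 1
    head_level: str = "deepest"
    n_classes: int = 4
    input_size: int = 180

    def with_toggles(self, mcfem: bool, ca: bool, bifpn: bool) -> "ModelConfig":
        cfg = ModelConfig(**{**asdict(self),
                             "backbone": BackboneConfig(**asdict(self.backbone))})
        cfg.mcfem_enabled = mcfem
        cfg.ca_enabled = ca
        cfg.bifpn_enabled = bifpn
        return cfg

    @classmethod
    def scaled_down(cls, **kw) -> "ModelConfig":
        """Quarter-width, depth-1 variant for CPU-scale training runs."""
        defaults = dict(
            backbone=BackboneConfig(depths=(1, 1, 1, 1),
                                    widths=(16, 64, 128, 256, 512),
                                    bottleneck_width=1),
            bifpn_width=40, input_size=64)
        defaults.update(kw)
        return cls(**defaults)

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "backbone": {"depths": list(self.backbone.depths),
                         "widths": list(self.backbone.widths),
                         "cardinality": self.backbone.cardinality,
                         "bottleneck_width": self.backbone.bottleneck_width,
                         "in_channels": self.backbone.in_channels},
            "mcfem": {"enabled": self.mcfem_enabled,
                      "dilations": list(self.mcfem_dilations)},
            "ca": {"enabled": self.ca_enabled, "reduction": self.ca_reduction},
            "bifpn": {"enabled": self.bifpn_enabled, "width": self.bifpn_width,
                      "layers": self.bifpn_layers, "head_level": self.head_level},
            "n_classes": self.n_classes,
            "input_size": self.input_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        bb = d.get("backbone", {})
        mc = d.get("mcfem", {})
        ca = d.get("ca", {})
        bf = d.get("bifpn", {})
        return cls(
            backbone=BackboneConfig(
                depths=tuple(bb.get("depths", (3, 4, 6, 3))),
                widths=tuple(bb.get("widths", (64, 256, 512, 1024, 2048))),
                cardinality=bb.get("cardinality", 32),
                bottleneck_width=bb.get("bottleneck_width", 4),
                in_channels=bb.get("in_channels", 1)),
            mcfem_enabled=mc.get("enabled", True),
            mcfem_dilations=tuple(mc.get("dilations", (1, 2, 3, 4))),
            ca_enabled=ca.get("enabled", True),
            ca_reduction=ca.get("reduction", 32),
            bifpn_enabled=bf.get("enabled", True),
            bifpn_width=bf.get("width", 160),
            bifpn_layers=bf.get("layers", 1),
            head_level=bf.get("head_level", "deepest"),
            n_classes=d.get("n_classes", 4),
            input_size=d.get("input_size", 180))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class MSCFPNet(Module):
    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 dtype=np.float64):
        super().__init__()
        cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = ResNeXtBackbone(cfg.backbone, rng=rng, dtype=dtype)
        stage_widths = cfg.backbone.widths[1:]
        self.mcfems = [Mcfem(w, dilations=cfg.mcfem_dilations, rng=rng,
                             dtype=dtype) for w in stage_widths] \
            if cfg.mcfem_enabled else []
        self.cas = [CoordAttention(w, reduction=cfg.ca_reduction, rng=rng,
                                   dtype=dtype) for w in stage_widths] \
            if cfg.ca_enabled else []
        if cfg.bifpn_enabled:
            self.harmonize = Harmonize(list(cfg.backbone.widths),
                                       cfg.bifpn_width, rng=rng, dtype=dtype)
            self.bifpn_layers = [BiFpnLayer(cfg.bifpn_width, rng=rng, dtype=dtype)
                                 for _ in range(cfg.bifpn_layers)]
            head_width = cfg.bifpn_width
        else:
            self.harmonize = None
            self.bifpn_layers = []
            head_width = cfg.backbone.widths[-1]
        self.head = ClassifierHead(head_width, cfg.n_classes,
                                   head_level=cfg.head_level, rng=rng,
                                   dtype=dtype)
        self._cache = None

    # -- forward ---------------------------------------------------------
    def forward_features(self, x) -> list[np.ndarray]:
        """Per-stage maps after the context/attention cascade of each stage."""
        feats = [self.backbone.stem(x)]
        h = self.backbone.pool(feats[0])
        for i, stage in enumerate(self.backbone.stages):
            h = stage(h)
            if self.mcfems:
                h = self.mcfems[i](h)
            if self.cas:
                h = self.cas[i](h)
            feats.append(h)
        return feats

    def forward(self, x):
        if x.ndim != 4:
            raise ValueError("expected a [N, C, H, W] batch")
        feats = self.forward_features(x)
        pyramid_shapes = []
        if self.harmonize is not None:
            p = self.harmonize(feats)
            for layer in self.bifpn_layers:
                pyramid_shapes.append([lv.shape for lv in p.levels])
                p = layer.forward(p)
            pyramid_shapes.append([lv.shape for lv in p.levels])
            logits = self.head.forward(p)
        else:
            logits = self.head.forward_map(feats[-1])
        self._cache = (x.dtype, pyramid_shapes)
        return logits

    # -- backward --------------------------------------------------------
    def backward(self, dlogits):
        dtype, pyramid_shapes = self._cache
        if self.harmonize is not None:
            dlevels = self.head.backward(dlogits)
            dlevels = self._fill(dlevels, pyramid_shapes[-1], dtype)
            for k in range(len(self.bifpn_layers) - 1, -1, -1):
                dlevels = self.bifpn_layers[k].backward(dlevels)
                dlevels = self._fill(dlevels, pyramid_shapes[k], dtype)
            dfeats = self.harmonize.backward(dlevels)
        else:
            dmap = self.head.backward(dlogits)
            dfeats = [None] * len(self.backbone.stages) + [dmap]
        grad = dfeats[-1]
        for i in range(len(self.backbone.stages) - 1, -1, -1):
            if self.cas:
                grad = self.cas[i].backward(grad)
            if self.mcfems:
                grad = self.mcfems[i].backward(grad)
            grad = self.backbone.stages[i].backward(grad)
            if i > 0 and dfeats[i] is not None:
                grad = grad + dfeats[i]
        grad = self.backbone.pool.backward(grad)
        if dfeats[0] is not None:
            grad = grad + dfeats[0]
        return self.backbone.stem.backward(grad)

    @staticmethod
    def _fill(dlevels, shapes, dtype):
        return [np.zeros(s, dtype=dtype) if g is None else g
                for g, s in zip(dlevels, shapes)]
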