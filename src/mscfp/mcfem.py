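"""Multi-scale context feature extraction: six branches, learned softmax fusion.

The module runs a 1x1 convolution, four 3x3 convolutions with dilation
rates 1-4 (receptive fields 1, 3, 5, 7, 9) and an identity branch in
parallel, combines the six same-shaped outputs as a convex combination
whose weights are the softmax of six learnable logits, and projects the
fused map with a final 1x1 convolution.  Placed after each backbone stage
so every stage sees context at several receptive-field sizes.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Param, ReLU, Sequential


def receptive_field(kernel: int, dilation: int) -> int:
    """Effective receptive field k + (k-1)(d-1) of a single dilated conv."""
    if kernel % 2 == 0:
        raise ValueError("kernel size must be odd")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    return kernel + (kernel - 1) * (dilation - 1)


def fusion_weights(z: np.ndarray) -> np.ndarray:
    """Softmax of the six branch logits: W_i = exp(Z_i) / sum_c exp(Z_c)."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (6,):
        raise ValueError("exactly six fusion logits expected")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite fusion logits")
    e = np.exp(z - z.max())
    return e / e.sum()


class Mcfem(Module):
    """Six-branch context module with learnable fusion logits.

    Parameters
    ----------
    channels : width of the feature map this module sits on (C -> C branches).
    dilations : dilation rates of the 3x3 branches (default 1, 2, 3, 4).
    norm : attach batch norm to each conv branch and the output projection.
        Disabling it gives the bias-free configuration used by the
        impulse-response and zero-propagation tests.
    """

    def __init__(self, channels: int, dilations: tuple = (1, 2, 3, 4),
                 norm: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.dilations = tuple(dilations)
        n_branches = len(self.dilations) + 2        # + 1x1 conv + identity
        if n_branches != 6:
            raise ValueError("the module is defined with six branches")

        def branch(conv):
            return Sequential(conv, BatchNorm2d(channels, dtype=dtype)) \
                if norm else Sequential(conv)

        self.branch_1x1 = branch(Conv2d(channels, channels, 1, rng=rng,
                                        dtype=dtype))
        self.branch_dilated = [
            branch(Conv2d(channels, channels, 3, padding=d, dilation=d,
                          rng=rng, dtype=dtype))
            for d in self.dilations
        ]
        self.logits = Param(np.zeros(6, dtype=dtype), "fusion_logits")
        reduce_layers = [Conv2d(channels, channels, 1, rng=rng, dtype=dtype)]
        if norm:
            reduce_layers += [BatchNorm2d(channels, dtype=dtype), ReLU()]
        self.reduce = Sequential(*reduce_layers)
        self._cache = None

    @property
    def weights(self) -> np.ndarray:
        return fusion_weights(self.logits.data)

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        w = self.weights
        outs = [self.branch_1x1(x)]
        outs += [b(x) for b in self.branch_dilated]
        outs.append(x)                              # identity branch
        fused = sum(wi * oi for wi, oi in zip(w, outs))
        self._cache = (outs, w)
        return self.reduce(fused)

    def backward(self, grad):
        outs, w = self._cache
        dfused = self.reduce.backward(grad)
        # gradient w.r.t. each normalized weight, then softmax-chain to logits
        dw = np.array([float((dfused * o).sum()) for o in outs])
        self.logits.grad += (w * (dw - float(w @ dw))).astype(self.logits.data.dtype)
        dx = self.branch_1x1.backward(w[0] * dfused)
        for wi, b in zip(w[1:5], self.branch_dilated):
            dx += b.backward(wi * dfused)
        dx += w[5] * dfused                         # identity branch
        return dx

    def branch_receptive_fields(self) -> list[int]:
        """Analytic receptive fields of the conv branches (1x1 then dilated)."""
        return [1] + [receptive_field(3, d) for d in self.dilations]
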