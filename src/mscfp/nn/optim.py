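"""Stochastic gradient descent with classical momentum and weight decay."""

from __future__ import annotations

import numpy as np

from .core import Param


class SGD:
    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("negative learning rate")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
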