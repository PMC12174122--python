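"""Minimal layer framework: parameters, module tree, train/eval modes.

Every layer implements ``forward(x)`` (caching what backward needs) and
``backward(grad)`` (returning the gradient w.r.t. its input while
accumulating parameter gradients in ``Param.grad``).  Composite modules
chain their children explicitly in both directions; there is no tape.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover
        return f"Param({self.name or 'unnamed'}, shape={self.data.shape})"


class Module:
    """Base class; children and params are discovered from attributes."""

    def __init__(self):
        self.training = True

    # -- tree walking ----------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_params(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Param):
                yield (f"{prefix}{name}", value)
        for cname, child in self.children():
            yield from child.named_params(prefix=f"{prefix}{cname}.")

    def params(self):
        return [p for _, p in self.named_params()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def astype(self, dtype):
        """Cast all parameters (and running stats) in place."""
        for p in self.params():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for _, child in self.children():
            child._cast_buffers(dtype)
        self._cast_buffers(dtype)
        return self

    def _cast_buffers(self, dtype):  # overridden by layers with buffers
        pass

    # -- state dict ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_params()}
        self._collect_buffers(state, "")
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_params():
            p.data = np.asarray(state[name]).astype(p.data.dtype)
            p.grad = np.zeros_like(p.data)
        self._assign_buffers(state, "")

    def _collect_buffers(self, state: dict, prefix: str):
        for name, value in vars(self).items():
            if name.startswith("_buf_"):
                state[f"{prefix}{name}"] = np.asarray(value).copy()
        for cname, child in self.children():
            child._collect_buffers(state, f"{prefix}{cname}.")

    def _assign_buffers(self, state: dict, prefix: str):
        for name in list(vars(self)):
            key = f"{prefix}{name}"
            if name.startswith("_buf_") and key in state:
                setattr(self, name, np.asarray(state[key]).copy())
        for cname, child in self.children():
            child._assign_buffers(state, f"{prefix}{cname}.")

    # -- interface -------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]
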