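"""Parameterised layers and a tiny module container on top of the autograd ops."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Module:
    """Container discovering parameters through attribute traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if strict and (missing or extra):
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, v in state.items():
            if k in params:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                params[k].data = v.astype(params[k].data.dtype).copy()


class Conv2d(Module):
    """Same-padded 3x3 (or 1x1) convolution with He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (k, k, c_in, c_out)).astype(DTYPE),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, dilation=self.dilation)


class ConvRelu(Conv2d):
    def __call__(self, x: Tensor) -> Tensor:
        return ag.relu(super().__call__(x))


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / f_in)
        self.w = Tensor(rng.normal(0.0, std, (f_in, f_out)).astype(DTYPE),
                        requires_grad=True)
        self.b = Tensor(np.zeros(f_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.w, self.b)
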