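"""Layer modules: parameter containers around the functional ops.

Weight initialisation is fan-in-scaled Gaussian drawn from an explicit
``numpy.random.Generator`` passed at construction, so a model seed fully
determines the initial state.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Parameter, Tensor


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, b in self.named_buffers():
            b[...] = state["buffer:" + name]


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | str = 0, bias: bool = True, dtype=np.float32):
        super().__init__()
        if padding == "same":
            padding = (kernel_size - 1) // 2
        self.stride = stride
        self.padding = int(padding)
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_features, in_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class BatchNorm1d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float64))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Dropout(Module):
    """Inverted dropout; ``rng`` is shared across the model for seed control."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


def count_parameters(module: Module) -> int:
    """Number of trainable scalars (tensors with ``requires_grad`` unset are skipped)."""
    return sum(p.data.size for p in module.parameters() if p.requires_grad)
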