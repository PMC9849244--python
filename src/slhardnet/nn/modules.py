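"""Layer/module abstraction over the autograd engine.

Modules own :class:`Parameter` tensors and non-trainable buffers (batch-norm
running statistics), discover submodules through attribute assignment, and
serialise to flat ``name -> ndarray`` dictionaries.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Identity",
    "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid", "MaxPool2d", "ConvBNReLU",
    "manual_seed", "get_rng",
]

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for parameter initialisation."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode --------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialisation -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)[:5]} "
                f"unexpected={sorted(extra)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]
        for k, b in bufs.items():
            b[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """He-initialised 2-D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, padding=0,
                 dilation=1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kh * kw
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(_RNG.normal(0.0, std, (out_ch, in_ch, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ops.conv2d(x, self.weight, self.bias,
                          stride=self.stride, padding=self.padding,
                          dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self._buffers["running_mean"] = np.zeros(ch, dtype=np.float32)
        self._buffers["running_var"] = np.ones(ch, dtype=np.float32)

    def forward(self, x):
        return ops.batchnorm2d(x, self.weight, self.bias,
                               self._buffers["running_mean"],
                               self._buffers["running_var"],
                               self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return ops.maxpool2d(x, self.kernel)


class ConvBNReLU(Module):
    """Conv → BatchNorm → ReLU, the standard block used throughout."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding=None,
                 dilation=1, relu: bool = True):
        super().__init__()
        if padding is None:
            k = kernel if isinstance(kernel, int) else max(kernel)
            padding = dilation * (k - 1) // 2
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, dilation,
                           bias=False)
        self.bn = BatchNorm2d(out_ch)
        self.relu = relu

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.relu else x
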