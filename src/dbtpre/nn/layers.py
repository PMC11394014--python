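"""Network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self.items))] = m
        self.items.append(m)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


def _param(arr) -> Tensor:
    return Tensor(arr, requires_grad=True)


class Conv2d(Module):
    """2-D convolution, He-normal initialization from the supplied rng."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = _param(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = _param(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = _param(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = _param(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gamma = _param(np.ones((1, channels, 1, 1)))
            self.beta = _param(np.zeros((1, channels, 1, 1)))
        else:
            self.gamma = self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        m = ag.mean(x, axis=(2, 3), keepdims=True)
        centered = x - m
        v = ag.mean(centered * centered, axis=(2, 3), keepdims=True)
        xn = centered / ag.sqrt(v + self.eps)
        if self.gamma is not None:
            xn = xn * self.gamma + self.beta
        return xn


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.steps = ModuleList(mods)

    def forward(self, x):
        for m in self.steps:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)
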