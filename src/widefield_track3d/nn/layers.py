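"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm2d, conv2d, maxpool2d, relu

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBNReLU", "MaxPool2d", "Sequential"]


class Module:
    """Base class: child modules and parameters discovered by attribute walk."""

    training: bool = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            src = state[name]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {p.data.shape}")
            p.data = src.astype(p.data.dtype).copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{i}.running_mean"].copy()
                m.running_var = state[f"__bn{i}.running_var"].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel // 2
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self.training, self.momentum, self.eps)


class ConvBNReLU(Module):
    """The conv → batch-norm → ReLU unit used throughout backbone and neck."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1, rng=None):
        self.conv = Conv2d(c_in, c_out, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        self.kernel = kernel
        self.stride = stride or kernel
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
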