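"""Layer/module containers with named parameters and Glorot initialisation."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composite of parameters and sub-modules, discovered by attribute order."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            yield from _walk(value, f"{prefix}{name}")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch for keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class ModuleList(list):
    pass


def _walk(value, name: str) -> Iterator[tuple[str, Parameter]]:
    if isinstance(value, Parameter):
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(f"{name}.")
    elif isinstance(value, ModuleList):
        for i, item in enumerate(value):
            yield from _walk(item, f"{name}.{i}")


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, bias: bool = True):
        k = kernel_size
        self.stride = stride
        self.weight = Parameter(glorot_uniform(
            rng, (out_channels, in_channels, k, k),
            fan_in=in_channels * k * k, fan_out=out_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 2, bias: bool = True):
        k = kernel_size
        self.stride = stride
        self.weight = Parameter(glorot_uniform(
            rng, (in_channels, out_channels, k, k),
            fan_in=in_channels * k * k, fan_out=out_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x, out_hw: tuple[int, int] | None = None):
        return F.conv_transpose2d(x, self.weight, self.bias,
                                  stride=self.stride, out_hw=out_hw)
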