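"""Layers and optimization on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "Conv1d", "BatchNorm", "Adam"]


class Module:
    """Minimal parameter container with recursive collection."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        seen: set[int] = set()
        for key, obj in self.__dict__.items():
            for name, p in _collect_named(obj, f"{prefix}{key}"):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append((name, p))
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for obj in self.__dict__.values():
            for m in _collect_modules(obj):
                out.extend(m.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def weight_parameters(self) -> list[Parameter]:
        """Weight matrices/kernels subject to L2; biases and norm scales excluded."""
        return [p for name, p in self.named_parameters()
                if p.ndim >= 2 and "norm" not in name]


def _collect(obj):
    if isinstance(obj, Parameter):
        yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect(item)
    elif isinstance(obj, dict):
        for item in obj.values():
            yield from _collect(item)


def _collect_named(obj, name):
    if isinstance(obj, Parameter):
        yield name, obj
    elif isinstance(obj, Module):
        yield from obj.named_parameters(prefix=name + ".")
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            yield from _collect_named(item, f"{name}.{i}")
    elif isinstance(obj, dict):
        for key, item in obj.items():
            yield from _collect_named(item, f"{name}.{key}")


def _collect_modules(obj):
    if isinstance(obj, Module):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_modules(item)
    elif isinstance(obj, dict):
        for item in obj.values():
            yield from _collect_modules(item)


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int | None = None) -> np.ndarray:
    """Small uniform initialization scaled by 1/sqrt(fan_in)."""
    if fan_in is None:
        fan_in = int(np.prod(shape[1:])) or 1
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(uniform_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, *, stride: int = 1, dilation: int = 1):
        self.weight = Parameter(
            uniform_init(rng, (out_channels, in_channels, kernel), in_channels * kernel))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias,
                         stride=self.stride, dilation=self.dilation, padding="same")


class BatchNorm(Module):
    """Batch normalization over the batch (and time, for [N, C, L] inputs) axes.

    Training mode normalizes with batch statistics and updates running
    moments; evaluation mode uses the running moments, so a record's output
    does not depend on its batch companions.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.norm_gamma = Parameter(np.ones(num_features))
        self.norm_beta = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def __call__(self, x: Tensor) -> Tensor:
        conv_format = x.ndim == 3
        axes = (0, 2) if conv_format else (0,)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
        else:
            shape = (1, -1, 1) if conv_format else (1, -1)
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        gamma = self.norm_gamma.reshape((1, -1, 1) if conv_format else (1, -1))
        beta = self.norm_beta.reshape((1, -1, 1) if conv_format else (1, -1))
        return xhat * gamma + beta

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
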