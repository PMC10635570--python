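"""Neural-network layers and the Adam optimizer on the autodiff core.

Layers follow the usual module pattern: a module owns named parameter
tensors, ``__call__`` builds the computation graph, and ``parameters()``
yields every trainable tensor. Only what the generative models here need is
implemented: 1-D (transposed) convolutions, dense layers, batch and
instance normalisation, leaky ReLU and sigmoid.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _buffers(self) -> list[tuple["Module", str]]:
        """Non-trainable state (running normalisation statistics)."""
        out: list[tuple[Module, str]] = []
        for name in ("running_mean", "running_var"):
            if isinstance(getattr(self, name, None), np.ndarray):
                out.append((self, name))
        for v in self.__dict__.values():
            children = v if isinstance(v, (list, tuple)) else [v]
            for item in children:
                if isinstance(item, Module):
                    out.extend(item._buffers())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array mapping of all parameters and buffers (checkpoints)."""
        out = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for i, (mod, name) in enumerate(self._buffers()):
            out[f"b{i}"] = getattr(mod, name).copy()
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = arrays[f"p{i}"]
            if src.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at parameter {i}")
            p.data = src.copy()
        for i, (mod, name) in enumerate(self._buffers()):
            if f"b{i}" in arrays:
                setattr(mod, name, arrays[f"b{i}"].copy())


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = 1.0 / np.sqrt(max(1, fan_in))
    return Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.w = _param(rng, (c_out, c_in, kernel), c_in * kernel)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.w, self.b, self.stride, self.pad)


class ConvTranspose1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.w = _param(rng, (c_in, c_out, kernel), c_in * kernel)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose1d(x, self.w, self.b, self.stride, self.pad)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = _param(rng, (d_in, d_out), d_in)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)


class BatchNorm1d(Module):
    """Normalises (N, C, L) inputs over batch and length per channel.

    Training mode uses batch statistics (and updates running estimates);
    eval mode uses the running estimates, so generation is deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.data.reshape(c)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(c)
        else:
            mean = Tensor(self.running_mean.reshape(1, c, 1))
            var = Tensor(self.running_var.reshape(1, c, 1))
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.weight.reshape(1, c, 1) + self.bias.reshape(1, c, 1)


class InstanceNorm1d(Module):
    """Normalises each (sample, channel) independently over length."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.affine = affine
        if affine:
            self.weight = Tensor(np.ones(channels), requires_grad=True)
            self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        mean = x.mean(axis=2, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=2, keepdims=True)
        xhat = (x - mean) * (var + self.eps) ** -0.5
        if self.affine:
            xhat = xhat * self.weight.reshape(1, c, 1) + self.bias.reshape(1, c, 1)
        return xhat


def set_training(module: Module, training: bool) -> None:
    for v in module.__dict__.values():
        if isinstance(v, Module):
            set_training(v, training)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Module):
                    set_training(item, training)
    if hasattr(module, "training"):
        module.training = training


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
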