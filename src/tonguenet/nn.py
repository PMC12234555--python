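"""Neural-network layers and optimisation on top of :mod:`tonguenet.autodiff`.

Conventions follow the usual deep-learning ones: activations are NCHW
tensors (or N×L×C token tensors inside transformer blocks), parameters are
float32, and initialisation is deterministic given the generator passed to
``init_parameters``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from scipy import stats as _st

from .autodiff import Tensor, conv2d, gelu

__all__ = ["Module", "Parameter", "Conv2d", "Linear", "LayerNorm",
           "BatchNorm2d", "ModuleList", "AdamW", "count_parameters"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight module container with recursive parameter discovery."""

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        if hasattr(self, "training"):
            self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def init_parameters(self, rng: np.random.Generator) -> None:
        """Initialise every submodule depth-first with the shared generator."""
        for _, child in self._children():
            child.init_parameters(rng)
        self.reset_parameters(rng)

    def reset_parameters(self, rng: np.random.Generator) -> None:  # override
        pass

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in d.items():
            if key.startswith("buffer:"):
                bufs[key[7:]][...] = arr
            else:
                params[key].data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return _st.truncnorm.rvs(-2.0, 2.0, scale=std, size=shape,
                             random_state=rng).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, *,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = True):
        k = kernel_size
        self.stride, self.padding, self.dilation, self.groups = \
            stride, padding, dilation, groups
        self.weight = Parameter(np.zeros((out_ch, in_ch // groups, k, k),
                                         dtype=np.float32))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def reset_parameters(self, rng: np.random.Generator) -> None:
        o, _, kh, kw = self.weight.shape
        fan_out = kh * kw * o // self.groups
        std = float(np.sqrt(2.0 / fan_out))
        self.weight.data[...] = rng.normal(0.0, std, self.weight.shape)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        self.weight = Parameter(np.zeros((in_f, out_f), dtype=np.float32))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def reset_parameters(self, rng: np.random.Generator) -> None:
        self.weight.data[...] = _trunc_normal(rng, self.weight.shape)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalises the trailing feature dimension of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over N,H,W with running statistics for eval."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.training = True
        self.weight = Parameter(np.ones(ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
            xn = xc * ((var + self.eps) ** -0.5)
        else:
            xn = (x - self.running_mean.reshape(shape)) * \
                (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters in `model`."""
    return int(sum(p.data.size for p in model.parameters()))


class AdamW(object):
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 6e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            if self.weight_decay and p.data.ndim > 1:  # no decay on norms/bias
                p.data *= 1 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
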