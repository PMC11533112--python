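"""Small neural-network building blocks on top of :mod:`protofrag.autodiff`.

Parameters are named tensors collected in flat dictionaries so that models
can be serialized as plain arrays and optimizers can walk them generically.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .autodiff import Tensor

__all__ = ["glorot", "zeros", "Linear", "MLP", "Adam", "cosine_lr", "clip_grad_norm"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter tensor."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Linear:
    """Affine map x @ W + b with parameters registered under a prefix."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 params: dict, prefix: str, bias: bool = True):
        self.W = glorot(rng, d_in, d_out)
        params[f"{prefix}.W"] = self.W
        self.b = None
        if bias:
            self.b = zeros((d_out,))
            params[f"{prefix}.b"] = self.b

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP:
    """Fully connected stack with a nonlinearity between layers."""

    def __init__(self, rng: np.random.Generator, dims: list[int], params: dict,
                 prefix: str, activation: Callable[[Tensor], Tensor] | None = None):
        self.layers = [
            Linear(rng, dims[i], dims[i + 1], params, f"{prefix}.lin{i}")
            for i in range(len(dims) - 1)
        ]
        self.activation = activation if activation is not None else (lambda t: t.relu())

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = self.activation(x)
        return x


class Adam:
    """Adam optimizer over a flat name → Tensor parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def cosine_lr(epoch: int, total_epochs: int, peak: float, floor: float = 0.0) -> float:
    """Cosine-annealed learning rate: ``peak`` at epoch 0, down to ``floor``."""
    if total_epochs <= 1:
        return peak
    frac = min(max(epoch / (total_epochs - 1), 0.0), 1.0)
    return floor + 0.5 * (peak - floor) * (1.0 + math.cos(math.pi * frac))


def clip_grad_norm(params: dict, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad**2).sum())
    total = math.sqrt(total)
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return total
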