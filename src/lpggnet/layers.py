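"""Trainable layers built on the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv1d, maxpool1d

__all__ = ["Conv1d", "BatchNorm1d", "Linear", "Dropout", "MaxPool1d"]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Conv1d:
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        fan_in = in_channels * kernel
        self.w = _glorot(rng, (out_channels, in_channels, kernel),
                         fan_in, out_channels * kernel)
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class BatchNorm1d:
    """Batch normalization over (batch, channels, length) per channel."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        c = self.gamma.data.shape[0]
        if train:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1))
            var = Tensor(self.running_var.reshape(1, c, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1) + self.beta.reshape(1, c, 1)

    def parameters(self):
        return [self.gamma, self.beta]


class Linear:
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.w = _glorot(rng, (in_features, out_features),
                         in_features, out_features)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class MaxPool1d:
    def __init__(self, width: int):
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.width)


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, train: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not train or self.p == 0:
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
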