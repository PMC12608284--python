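"""Neural-network layers built on the autodiff engine.

Parameters are plain :class:`~difnet.nn.tensor.Tensor` objects with
``requires_grad=True``; modules recursively expose them through
``parameters()``.  Stochastic layers (dropout) draw from a generator installed
with ``seed_dropout``, so a model seeded once is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "SpatialConv",
    "Dropout",
    "LayerNorm",
    "BatchNorm1d",
]


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            for m in _collect_modules(value):
                mods.extend(m.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def seed_dropout(self, rng: np.random.Generator) -> "Module":
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                bufs.extend((m.running_mean, m.running_var))
        return bufs

    def state(self) -> list[np.ndarray]:
        """Parameters plus normalization running statistics — everything a
        checkpoint needs to reproduce the forward pass."""
        return [p.data.copy() for p in self.parameters()] + [
            b.copy() for b in self._buffers()
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        slots = self.parameters() + self._buffers()
        if len(slots) != len(state):
            raise ValueError("state does not match parameter/buffer list")
        for slot, s in zip(slots, state):
            target = slot.data if isinstance(slot, Tensor) else slot
            if target.shape != s.shape:
                raise ValueError(f"shape mismatch {target.shape} vs {s.shape}")
            target[...] = s


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(1.0 / fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.weight = Tensor(np.zeros((d_in, d_out)), requires_grad=True)
        else:
            self.weight = _param(rng, (d_in, d_out), d_in)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D cross-correlation, 'same' or 'causal' padded, optional dilation."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: str = "same", bias: bool = True):
        super().__init__()
        self.dilation = dilation
        self.padding = padding
        self.weight = _param(rng, (c_out, c_in, kernel), c_in * kernel)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias,
                        dilation=self.dilation, padding=self.padding)


class SpatialConv(Module):
    """Depthwise electrode-collapsing convolution: (B,F,C,T) -> (B,F*M,T)."""

    def __init__(self, n_filters: int, n_channels: int, multiplier: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng, (n_filters, multiplier, n_channels), n_channels)

    def __call__(self, x: Tensor) -> Tensor:
        return x.spatial_collapse(self.weight)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without seed_dropout")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class BatchNorm1d(Module):
    """Per-channel normalization of (B, C, T) over batch and time.

    Running statistics (momentum 0.1) are used in eval mode.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var
            )
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
            centered = x - mu
        inv = (var + self.eps) ** -0.5
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return centered * inv * g + b
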