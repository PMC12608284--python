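"""Optimizers and loss functions."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "cross_entropy"]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels.

    Composed from autodiff primitives via a numerically stable log-sum-exp.
    """
    labels = np.asarray(labels)
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)
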