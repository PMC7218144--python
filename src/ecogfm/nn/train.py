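"""Optimization utilities: stable binary cross-entropy and Adam."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, _make, _sigmoid


def sigmoid(z: np.ndarray) -> np.ndarray:
    return _sigmoid(np.asarray(z, dtype=np.float64))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from logits (numerically stable)."""
    z = logits.data.ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    loss = np.mean(np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z))))

    def backward(g):
        if logits.requires_grad:
            dz = (_sigmoid(z) - y) / len(y) * g
            logits._accumulate(dz.reshape(logits.data.shape))

    return _make(loss, (logits,), backward)


@dataclass
class TrainConfig:
    """Knobs of the stochastic optimization loop.

    Epoch count is bounded by early stopping on a held-out channel-grouped
    validation split (no channel contributes to both optimization and the
    stopping rule).
    """

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.3
    patience: int = 10
    val_fraction: float = 0.15
    seed: int = 0


class AdamOptimizer:
    """Adam with bias correction over a fixed list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
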