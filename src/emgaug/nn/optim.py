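"""Optimizers and training losses for the numpy engine."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGDMomentum", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def bce_with_logits(logits: np.ndarray,
                    labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on raw logits (numerically stable form).

    Returns ``(mean loss, gradient wrt logits)``.  For a perfectly
    confident correct classifier the loss tends to 0; for a perfectly
    confident wrong one it diverges.
    """
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    loss = np.mean(np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * y)
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.reshape(np.shape(logits))


class Adam:
    """Adam with Keras-style defaults (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGDMomentum:
    """Plain momentum SGD; fallback optimizer for style optimization."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2,
                 momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.vel):
            v *= self.momentum
            v -= self.lr * g
            p += v
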