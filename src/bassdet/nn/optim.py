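"""Adam optimizer and cosine-annealing schedule."""

from __future__ import annotations

import math

import numpy as np

from .engine import Param

__all__ = ["Adam", "cosine_lr", "clip_grad_norm"]


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = math.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(base_lr: float, step: int, total_steps: int,
              floor_fraction: float = 0.01) -> float:
    """Single-cycle cosine decay from ``base_lr`` to ``base_lr * floor_fraction``."""
    if total_steps <= 1:
        return base_lr
    t = min(step, total_steps - 1) / (total_steps - 1)
    lo = base_lr * floor_fraction
    return lo + 0.5 * (base_lr - lo) * (1 + math.cos(math.pi * t))
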