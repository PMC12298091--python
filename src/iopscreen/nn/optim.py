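"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "AdamW", "warmup_cosine"]


class Adam:
    """Adam with optional L2-coupled weight decay (set via subclass for AdamW)."""

    decoupled = False

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mh = self._m[i] / (1 - b1**self._t)
            vh = self._v[i] / (1 - b2**self._t)
            upd = mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay and self.decoupled:
                upd = upd + self.weight_decay * p.data
            p.data = p.data - self.lr * upd


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    decoupled = True


def warmup_cosine(step: int, total_steps: int, base_lr: float,
                  warmup_steps: int = 0, min_lr: float = 0.0) -> float:
    """Linear warmup followed by cosine decay to ``min_lr``."""
    if total_steps <= 0:
        return base_lr
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    frac = min(max(step - warmup_steps, 0) / span, 1.0)
    return min_lr + 0.5 * (base_lr - min_lr) * (1 + math.cos(math.pi * frac))
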