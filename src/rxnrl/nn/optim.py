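"""Optimizers for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    """Adam with optional gradient-norm clipping."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def global_grad_norm(self) -> float:
        sq = 0.0
        for p in self.params:
            if p.grad is not None:
                sq += float((p.grad**2).sum())
        return float(np.sqrt(sq))

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            norm = self.global_grad_norm()
            if not np.isfinite(norm):
                raise FloatingPointError("non-finite gradient norm")
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
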