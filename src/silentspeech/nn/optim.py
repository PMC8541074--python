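"""Adaptive-moment (Adam) optimizer with a step-based learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam"]


class Adam:
    """Standard Adam with bias correction.

    ``lr`` may be reassigned between steps; :meth:`scheduled_lr` implements
    the divide-by-ten schedule used for training (÷10 at each boundary
    step, applied at most twice).
    """

    def __init__(self, params: list[Tensor], lr: float = 0.01,
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
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    @staticmethod
    def scheduled_lr(lr0: float, iteration: int, boundaries: tuple[int, ...] = (500, 1000)) -> float:
        """Learning rate at a given optimizer step (1-based).

        Starts at ``lr0`` and divides by 10 when the step passes each
        boundary: 0.01 → 0.001 at step 501 → 0.0001 at step 1001.
        """
        drops = sum(iteration > b for b in boundaries)
        return lr0 / (10.0 ** drops)
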