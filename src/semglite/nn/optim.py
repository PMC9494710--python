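"""Optimizers: stochastic gradient descent with momentum, and Adam."""

from __future__ import annotations

import numpy as np

from .layers import Param

F32 = np.float32


class SGDM:
    """SGD with classical momentum (default 0.9)."""

    def __init__(self, params: list[Param], momentum: float = 0.9) -> None:
        self.params = params
        self.momentum = F32(momentum)
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        lr = F32(lr)
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= lr * p.grad
            p.value += v


class Adam:
    """Adam with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(
        self,
        params: list[Param],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * np.square(p.grad)
            p.value -= F32(lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
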