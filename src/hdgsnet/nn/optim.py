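"""Adam optimizer for the numpy layer engine."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.g
            v *= b2
            v += (1.0 - b2) * p.g * p.g
            p.v -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
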