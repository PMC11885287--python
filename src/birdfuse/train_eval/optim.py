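"""Adam and RMSprop updates over lists of :class:`~birdfuse.encoders.layers.Param`."""

from __future__ import annotations

import numpy as np

from ..encoders.layers import Param
from ..errors import InvalidConfigError

__all__ = ["Adam", "RMSprop", "make_optimizer"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class RMSprop:
    def __init__(self, params: list[Param], lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, sq in zip(self.params, self.sq):
            sq *= self.rho
            sq += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def make_optimizer(name: str, params: list[Param], lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "rmsprop":
        return RMSprop(params, lr=lr)
    raise InvalidConfigError(f"unknown optimizer {name!r}")
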