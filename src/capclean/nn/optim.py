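"""Optimisers: SGD with momentum and Nadam.

Nadam follows Dozat's formulation (Adam with Nesterov momentum): with biased
moments ``m, v`` and decay rates ``b1, b2`` at step ``t``,

    m_hat = b1*m/(1 - b1^(t+1)) + (1 - b1)*g/(1 - b1^t)
    v_hat = v/(1 - b2^t)
    theta -= lr * m_hat / (sqrt(v_hat) + eps)
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Nadam", "make_optimizer"]


class _Optimizer:
    def __init__(self, lr: float) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.t = 0
        self._slots: dict[int, dict[str, np.ndarray]] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self._update(i, p, g.astype(np.float32))

    def _slot(self, i: int, name: str, like: np.ndarray) -> np.ndarray:
        return self._slots.setdefault(i, {}).setdefault(name, np.zeros_like(like))

    def _update(self, i: int, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr: float = 0.0005, momentum: float = 0.9, decay: float = 0.0) -> None:
        super().__init__(lr)
        self.momentum = momentum
        self.decay = decay

    def _update(self, i: int, p: np.ndarray, g: np.ndarray) -> None:
        lr = self.lr / (1.0 + self.decay * self.t)
        vel = self._slot(i, "vel", p)
        vel *= self.momentum
        vel -= lr * g
        p += vel


class Nadam(_Optimizer):
    def __init__(
        self,
        lr: float = 0.0005,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, i: int, p: np.ndarray, g: np.ndarray) -> None:
        b1, b2 = self.beta1, self.beta2
        t = self.t
        m = self._slot(i, "m", p)
        v = self._slot(i, "v", p)
        m *= b1
        m += (1 - b1) * g
        v *= b2
        v += (1 - b2) * g * g
        m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def make_optimizer(name: str, lr: float, momentum: float = 0.9, decay: float = 0.0) -> _Optimizer:
    name = name.lower()
    if name == "sgd":
        return SGD(lr=lr, momentum=momentum, decay=decay)
    if name == "nadam":
        return Nadam(lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
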