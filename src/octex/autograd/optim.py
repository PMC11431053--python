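"""Stochastic gradient descent with classical momentum.

Update rule: v <- mu * v + g;  w <- w - lr * v. The learning rate may be
changed between steps (the trainer anneals it per batch with a cosine
schedule).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params: list[Tensor] = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
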