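"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .tensor import Tensor


class SGD:
    """v <- mu*v + g; p <- p - lr*v, with optional L2 weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.05,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        self.params: List[Tensor] = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity: List[Optional[np.ndarray]] = [None] * len(self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._velocity[i]
            v = g.copy() if v is None else self.momentum * v + g
            self._velocity[i] = v
            p.data = p.data - self.lr * v
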