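"""Adam / AdamW over (param, grad) array pairs, updating in place."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with optional decoupled weight decay.

    ``decoupled=True`` applies the weight decay directly to the parameters
    (AdamW); ``decoupled=False`` adds it to the gradient (classic Adam + L2).
    """

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-4,
        weight_decay: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        decoupled: bool = True,
    ):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g if self.decoupled else g + self.wd * p
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.decoupled:
                update = update + self.wd * p
            p -= (self.lr * update).astype(p.dtype)
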