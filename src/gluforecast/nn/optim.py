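"""Adam optimizer (Kingma & Ba) over a Sequential's parameter dicts."""

from __future__ import annotations

import numpy as np

from .layers import Sequential

__all__ = ["Adam"]


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in net.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in net.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.net.layers, self.m, self.v):
            for k, p in layer.params.items():
                grad = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * grad
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * grad**2
                p -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)
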