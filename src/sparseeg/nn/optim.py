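"""Adaptive-moment (Adam) optimizer over (layer, key) parameter references."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    def __init__(
        self,
        params: list[tuple[Layer, str]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(layer.params[k]) for layer, k in params]
        self._v = [np.zeros_like(layer.params[k]) for layer, k in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (layer, k) in enumerate(self.params):
            g = layer.grads.get(k)
            if g is None:
                continue
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            layer.params[k] = layer.params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
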