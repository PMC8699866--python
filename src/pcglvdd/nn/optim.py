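"""Adam optimizer operating in place on a network's parameter dicts."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        for i, name, params, _ in net.param_items():
            key = (i, name)
            self._m[key] = np.zeros_like(params[name])
            self._v[key] = np.zeros_like(params[name])

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for i, name, params, grads in self.net.param_items():
            g = grads.get(name)
            if g is None:
                continue
            key = (i, name)
            m = self._m[key]
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[name] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
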