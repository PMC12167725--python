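"""Adaptive moment estimation with Nesterov momentum (Nadam)."""

from __future__ import annotations

import numpy as np

__all__ = ["Nadam"]


class Nadam:
    """Adam with a Nesterov-style lookahead on the first moment.

    Update (Dozat 2016), per parameter with gradient g at step t:

        m <- b1 m + (1-b1) g            v <- b2 v + (1-b2) g^2
        m_hat = m / (1 - b1^t)          v_hat = v / (1 - b2^t)
        theta <- theta - lr * (b1 * m_hat + (1-b1) g / (1 - b1^t))
                          / (sqrt(v_hat) + eps)

    Moment decay rates and epsilon follow the published defaults.
    """

    def __init__(self, param_items, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.items = list(param_items)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p[k]) for p, _, k in self.items]
        self.v = [np.zeros_like(p[k]) for p, _, k in self.items]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, (params, grads, key) in enumerate(self.items):
            g = grads[key]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / c1
            v_hat = self.v[i] / c2
            update = lr * (b1 * m_hat + (1 - b1) * g / c1) / (np.sqrt(v_hat) + self.eps)
            params[key] = (params[key] - update).astype(np.float32)
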