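"""Adam optimizer over a dict of named parameter arrays."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive-moment gradient descent with bias-corrected moments."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        """One in-place update; ``lr`` overrides the stored rate (schedulers)."""
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(self.params[k].dtype, copy=False)
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            self.params[k] -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
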