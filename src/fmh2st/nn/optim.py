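"""Adam on flattened nested-dict parameters, with global-norm gradient clipping."""

from __future__ import annotations

import numpy as np
from autograd.misc.flatten import flatten


class Adam:
    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        flat, self._unflatten = flatten(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        x, unflat = flatten(params)
        g, _ = flatten(grads)
        if self.clip_norm is not None:
            norm = np.linalg.norm(g)
            if norm > self.clip_norm:
                g = g * (self.clip_norm / norm)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        x = x - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return unflat(x)
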