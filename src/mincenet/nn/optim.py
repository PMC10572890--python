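"""Optimisers for the NumPy layer stack."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    """Adam with bias-corrected first/second moments (Kingma & Ba defaults)."""

    def __init__(self, parameters, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.parameters = [p for p in parameters if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.parameters]
        self._v = [np.zeros_like(p.value) for p in self.parameters]

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        scale = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.parameters, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= scale * m / (np.sqrt(v) + self.eps)
            if self.weight_decay:
                # decoupled decay, applied to multi-dimensional weights only
                # (biases and batch-norm scale/shift are left undecayed)
                if p.value.ndim > 1:
                    p.value *= 1.0 - self.lr * self.weight_decay


class SGD:
    def __init__(self, parameters, lr=1e-2, momentum=0.0):
        self.parameters = [p for p in parameters if p.trainable]
        self.lr, self.momentum = lr, momentum
        self._v = [np.zeros_like(p.value) for p in self.parameters]

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0

    def step(self):
        for p, v in zip(self.parameters, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
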