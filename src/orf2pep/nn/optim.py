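"""Optimizers: Adam and Adafactor."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Optimizer:
    def __init__(self, params):
        self.params: list[Tensor] = list(params)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):  # pragma: no cover - interface
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Adafactor(Optimizer):
    """Adafactor with factored second moments (matrices) and update clipping.

    Uses an externally supplied constant learning rate (no relative-step
    schedule) and no first moment, following the memory-efficient variant.
    """

    def __init__(self, params, lr: float = 2e-5, eps1: float = 1e-30,
                 clip_threshold: float = 1.0, decay_exponent: float = -0.8):
        super().__init__(params)
        self.lr = lr
        self.eps1 = eps1
        self.clip = clip_threshold
        self.decay_exponent = decay_exponent
        self.t = 0
        self.state = []
        for p in self.params:
            if p.data.ndim >= 2:
                r = np.zeros(p.data.shape[:-1], dtype=np.float64)
                c = np.zeros(p.data.shape[:-2] + p.data.shape[-1:], dtype=np.float64)
                self.state.append(("factored", r, c))
            else:
                self.state.append(("full", np.zeros(p.data.shape, dtype=np.float64), None))

    def step(self):
        self.t += 1
        beta2t = 1.0 - self.t ** self.decay_exponent
        for p, st in zip(self.params, self.state):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            g2 = g * g + self.eps1
            kind, a, b = st
            if kind == "factored":
                a *= beta2t
                a += (1 - beta2t) * g2.mean(axis=-1)
                b *= beta2t
                b += (1 - beta2t) * g2.mean(axis=-2)
                denom = a[..., None] * b[..., None, :]
                denom /= np.maximum(a.mean(axis=-1, keepdims=True)[..., None], 1e-30)
                u = g / np.sqrt(denom)
            else:
                a *= beta2t
                a += (1 - beta2t) * g2
                u = g / np.sqrt(a)
            rms_u = np.sqrt((u * u).mean())
            u /= max(1.0, rms_u / self.clip)
            p.data -= (self.lr * u).astype(p.data.dtype)
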