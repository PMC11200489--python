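"""Adam optimiser over a list of layers."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    """Adam with optional global gradient-norm clipping.

    Clipping tames the large first-step gradients of a freshly initialised
    deep ReLU stack, which would otherwise drive units irreversibly dead.
    """

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = None,
        warmup_steps: int = 0,
    ) -> None:
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers
        ]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        if self.clip_norm is not None:
            sq = 0.0
            for lay in self.layers:
                for g in lay.grads.values():
                    sq += float(np.sum(np.square(g, dtype=np.float64)))
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = np.float32(self.clip_norm / norm)
                for lay in self.layers:
                    for k in lay.grads:
                        lay.grads[k] = lay.grads[k] * scale
        self.t += 1
        lr = self.lr
        if self.warmup_steps and self.t <= self.warmup_steps:
            # linear warmup damps the chaotic first steps of a fresh ReLU
            # stack (Adam's per-coordinate steps are otherwise full-size
            # immediately, which kills units irreversibly)
            lr = self.lr * self.t / self.warmup_steps
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads.get(k)
                if g is None:
                    continue
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


class SGD:
    """Plain SGD with classical momentum (optional lr warmup)."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 0.05,
        momentum: float = 0.9,
        warmup_steps: int = 0,
    ) -> None:
        self.layers = layers
        self.lr, self.mu = lr, momentum
        self.warmup_steps = warmup_steps
        self.t = 0
        self.v = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers
        ]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        lr = self.lr
        if self.warmup_steps and self.t <= self.warmup_steps:
            lr = self.lr * self.t / self.warmup_steps
        for lay, v in zip(self.layers, self.v):
            for k, p in lay.params.items():
                g = lay.grads.get(k)
                if g is None:
                    continue
                v[k] = self.mu * v[k] + g
                p -= lr * v[k]
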