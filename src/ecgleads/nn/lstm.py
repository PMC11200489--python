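"""LSTM layer with full backpropagation through time.

Gate order is (input, forget, cell, output). Weights are orthogonally
initialised per gate block; the forget-gate bias starts at 1 so early
training keeps long-range context. ``reverse=True`` processes the sequence
right-to-left (used to build bidirectional front ends).
"""

from __future__ import annotations

import numpy as np

from . import init
from .layers import Layer


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    def __init__(
        self,
        d_in: int,
        hidden: int,
        reverse: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.d_in, self.h, self.reverse = d_in, hidden, reverse
        rng = rng or np.random.default_rng(0)
        self.params["Wx"] = np.concatenate(
            [init.orthogonal((d_in, hidden), rng) for _ in range(4)], axis=1
        )
        self.params["Wh"] = np.concatenate(
            [init.orthogonal((hidden, hidden), rng) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0  # forget gate
        self.params["b"] = b

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(n, T, d_in) → full hidden sequence (n, T, h), in input time order."""
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected input width {self.d_in}, got {x.shape[-1]}")
        if self.reverse:
            x = x[:, ::-1]
        n, T, _ = x.shape
        h = self.h
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        pre = x.reshape(n * T, -1) @ Wx
        pre = pre.reshape(n, T, 4 * h) + b
        H = np.zeros((n, T, h), dtype=np.float32)
        cache = []
        ht = np.zeros((n, h), dtype=np.float32)
        ct = np.zeros((n, h), dtype=np.float32)
        for t in range(T):
            z = pre[:, t] + ht @ Wh
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = ct
            ct = f * c_prev + i * g
            tc = np.tanh(ct)
            h_prev = ht
            ht = o * tc
            H[:, t] = ht
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._cache = (x, cache)
        return H[:, ::-1] if self.reverse else H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        if self.reverse:
            dH = dH[:, ::-1]
        n, T, _ = x.shape
        h = self.h
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx, dtype=np.float64)
        dWh = np.zeros_like(Wh, dtype=np.float64)
        db = np.zeros(4 * h, dtype=np.float64)
        dx = np.empty_like(x)
        dht = np.zeros((n, h), dtype=np.float32)
        dct = np.zeros((n, h), dtype=np.float32)
        dz_all = np.empty((n, T, 4 * h), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dht = dht + dH[:, t].astype(np.float32)
            do = dht * tc
            dct = dct + dht * o * (1 - tc**2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dz_all[:, t] = dz
            dWh += h_prev.T.astype(np.float64) @ dz.astype(np.float64)
            dht = dz @ Wh.T
            dct = dct * f
        dz2 = dz_all.reshape(n * T, 4 * h)
        dWx += x.reshape(n * T, -1).T.astype(np.float64) @ dz2.astype(np.float64)
        db += dz2.sum(axis=0)
        dx = (dz2 @ Wx.T).reshape(n, T, self.d_in)
        self.grads["Wx"] = dWx.astype(np.float32)
        self.grads["Wh"] = dWh.astype(np.float32)
        self.grads["b"] = db.astype(np.float32)
        return dx[:, ::-1] if self.reverse else dx
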