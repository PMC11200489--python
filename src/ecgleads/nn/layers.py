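"""Feed-forward layers: grouped 1-D convolution, pooling, linear, losses.

Each layer stores parameters in ``params`` (name → array) and caches what
backward needs during forward; ``backward(dy)`` returns dx and fills
``grads``. Convolutional tensors are channels-last — (batch, group, time,
channels) — so the im2col gather feeding the per-group GEMM is
cache-friendly; the data gradient is computed as a full convolution with the
flipped kernel (another GEMM) rather than a scatter loop. Padding is
"same"-style: output length is ceil(L / stride), even kernels padding one
sample more on the right.
"""

from __future__ import annotations

import numpy as np

from . import init


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    g = p
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(np.float32)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


def _same_pad(L: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-L // stride)  # ceil
    total = max(0, (out - 1) * stride + k - L)
    return out, total // 2, total - total // 2


class Conv1dGrouped(Layer):
    """1-D convolution applied independently per lead (grouped, no mixing).

    Input (n, G, L, C_in) → output (n, G, L_out, C_out); each of the G groups
    (ECG leads) has its own kernel bank ``W[g]`` of shape (C_in, k, C_out),
    so no parameter ever connects two leads. ReLU when ``activation`` is set.
    """

    def __init__(
        self,
        groups: int,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        activation: bool = True,
        rng: np.random.Generator | None = None,
        use_bias: bool = False,
    ) -> None:
        super().__init__()
        self.G, self.c_in, self.c_out = groups, c_in, c_out
        self.k, self.stride = kernel, stride
        self.activation = activation
        self.use_bias = use_bias
        rng = rng or np.random.default_rng(0)
        self.params["W"] = init.kaiming_normal(
            (groups, c_in, kernel, c_out), fan_in=c_in * kernel, rng=rng
        )
        if use_bias:
            self.params["b"] = np.zeros((groups, c_out), dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, G, L, C = x.shape
        k, s = self.k, self.stride
        Lout, pl, pr = _same_pad(L, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        W = self.params["W"]
        # y[:, :, t] = Σ_j xp[:, :, s·t+j] @ W[:, :, j]: one batched GEMM per
        # kernel offset on contiguous slices (no im2col gather).
        y = np.zeros((n, G, Lout, self.c_out), dtype=np.float32)
        for j in range(k):
            y += np.matmul(xp[:, :, j : j + s * Lout : s, :], W[:, :, j, :])
        self._cache = (xp, L, Lout, pl)
        if self.use_bias:
            y += self.params["b"][None, :, None, :]
        if self.activation:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation:
            dy = np.where(self._mask, dy, 0.0)
        xp, L, Lout, pl = self._cache
        k, s = self.k, self.stride
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        dyt = np.ascontiguousarray(dy)
        for j in range(k):
            sl = xp[:, :, j : j + s * Lout : s, :]
            # (G, C, c_out) summed over batch and time
            dW[:, :, j, :] = np.einsum("ngtc,ngto->gco", sl, dyt, optimize=True)
            dxp[:, :, j : j + s * Lout : s, :] += np.matmul(
                dyt, W[:, :, j, :].transpose(0, 2, 1)
            )
        self.grads["W"] = dW
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 2)).astype(np.float32)
        self._cache = None
        return dxp[:, :, pl : pl + L, :]


class MaxPool1dSame(Layer):
    """Size-k / stride-1 max pooling over time with edge padding.

    Length-preserving; backward routes each gradient to the first window
    position attaining the maximum.
    """

    def __init__(self, kernel: int = 3) -> None:
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        L = x.shape[2]
        _, pl, pr = _same_pad(L, self.k, 1)
        xp = np.pad(
            x, ((0, 0), (0, 0), (pl, pr), (0, 0)), constant_values=-np.inf
        )
        out = xp[:, :, 0:L, :]
        for j in range(1, self.k):
            out = np.maximum(out, xp[:, :, j : j + L, :])
        self._cache = (xp, out, pl, L)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, out, pl, L = self._cache
        dxp = np.zeros_like(xp, dtype=dy.dtype)
        taken = np.zeros(dy.shape, dtype=bool)
        for j in range(self.k):
            sel = (xp[:, :, j : j + L, :] == out) & ~taken
            dxp[:, :, j : j + L, :] += dy * sel
            taken |= sel
        return dxp[:, :, pl : pl + L, :]


class Linear(Layer):
    """Affine map with optional ReLU."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        activation: bool = False,
        rng: np.random.Generator | None = None,
        init_scheme: str = "kaiming",
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if init_scheme == "orthogonal":
            self.params["W"] = init.orthogonal((d_in, d_out), rng)
        else:
            # gain 2 under a ReLU, gain 1 for a purely linear output layer
            self.params["W"] = init.kaiming_normal(
                (d_in, d_out), d_in, rng, gain=2.0 if activation else 1.0
            )
        self.params["b"] = np.zeros(d_out, dtype=np.float32)
        self.activation = activation

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        y = x @ self.params["W"] + self.params["b"]
        if self.activation:
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation:
            dy = dy * self._mask
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] = (x2.T @ dy2).astype(np.float32)
        self.grads["b"] = dy2.sum(axis=0).astype(np.float32)
        return dy @ self.params["W"].T
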