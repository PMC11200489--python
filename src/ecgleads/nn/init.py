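"""Weight initialisers (variance-scaling and orthogonal)."""

from __future__ import annotations

import numpy as np


def kaiming_normal(
    shape: tuple[int, ...],
    fan_in: int,
    rng: np.random.Generator,
    gain: float = 2.0,
) -> np.ndarray:
    """Variance-scaling normal init: std = sqrt(gain / fan_in).

    gain = 2 (He/Kaiming) for ReLU-activated layers; gain = 1 for a linear
    output layer, which no rectifier follows.
    """
    std = np.sqrt(gain / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def orthogonal(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Orthogonal matrix of the given (rows, cols) shape via QR."""
    rows, cols = shape
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix the sign ambiguity for determinism
    if rows < cols:
        q = q.T
    return np.ascontiguousarray(q).astype(np.float32)
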