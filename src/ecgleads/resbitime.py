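"""ResBiTime: residual bidirectional-LSTM heartbeat classifier.

Beats restricted to the k selected leads (time axis 325, features per step =
k) enter a bidirectional LSTM front end. A stack of residual blocks follows;
each block runs two parallel unidirectional LSTMs — one reading the previous
block's output, one re-reading the front end's output — combines them through
width-matching linear maps (element-wise sum) and adds the block input as a
shortcut. The final time step of the last block feeds a fully connected head
(ReLU + dropout) ending in 9 class scores. All weight matrices are
orthogonally initialised; the shortcut keeps widths matched so it can be
switched off for ablation without changing any shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import BEAT_LEN, BeatSet, lead_index
from .nn import LSTM, Adam, Linear, cross_entropy, softmax


@dataclass
class ResBiTimeConfig:
    """Classifier hyperparameters (training defaults are the published recipe).

    hidden is the per-direction LSTM width; block LSTMs use the same width and
    the running feature width is 2·hidden throughout.
    """

    hidden: int = 64
    blocks: int = 2
    fc_width: int = 64
    dropout: float = 0.2
    use_shortcut: bool = True
    pool: str = "last"  # "last" final time step | "mean" over time
    batch_size: int = 32
    epochs: int = 30
    lr: float = 1e-3
    seed: int = 0
    #: standardise each input lead by its training-set mean/std (stored on
    #: the model; an untrained model passes inputs through unchanged)
    standardize_inputs: bool = True
    #: global gradient-norm clip (None disables) and linear lr-warmup
    #: fraction — both stabilise LSTM training against loss spikes
    clip_norm: float | None = 1.0
    warmup_frac: float = 0.1

    def __post_init__(self) -> None:
        if min(self.hidden, self.blocks, self.fc_width, self.batch_size) < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pool not in ("last", "mean"):
            raise ValueError("pool must be 'last' or 'mean'")


class ResBiTimeModel:
    def __init__(self, k: int, num_classes: int = 9, cfg: ResBiTimeConfig | None = None):
        if k < 1:
            raise ValueError("need at least one input lead")
        self.k, self.num_classes = k, num_classes
        self.cfg = cfg or ResBiTimeConfig()
        c = self.cfg
        rng = np.random.default_rng(c.seed)
        d = 2 * c.hidden
        self.front_f = LSTM(k, c.hidden, rng=rng)
        self.front_b = LSTM(k, c.hidden, reverse=True, rng=rng)
        self.blocks: list[dict] = []
        for _ in range(c.blocks):
            self.blocks.append(
                dict(
                    prev=LSTM(d, c.hidden, rng=rng),
                    orig=LSTM(d, c.hidden, rng=rng),
                    comb_prev=Linear(c.hidden, d, rng=rng, init_scheme="orthogonal"),
                    comb_orig=Linear(c.hidden, d, rng=rng, init_scheme="orthogonal"),
                )
            )
        self.fc1 = Linear(d, c.fc_width, activation=True, rng=rng, init_scheme="orthogonal")
        self.fc2 = Linear(c.fc_width, num_classes, rng=rng, init_scheme="orthogonal")
        self._drop_rng = np.random.default_rng(c.seed + 1)
        self.input_offset = np.zeros(k, dtype=np.float32)
        self.input_scale = np.ones(k, dtype=np.float32)

    @property
    def layers(self) -> list:
        out = [self.front_f, self.front_b]
        for b in self.blocks:
            out += [b["prev"], b["orig"], b["comb_prev"], b["comb_orig"]]
        return out + [self.fc1, self.fc2]

    def _validate(self, beats: np.ndarray) -> np.ndarray:
        beats = np.asarray(beats, dtype=np.float32)
        if beats.ndim == 2:
            beats = beats[None]
        if beats.shape[1:] != (self.k, BEAT_LEN):
            raise ValueError(
                f"beats must be n×{self.k}×{BEAT_LEN}, got {beats.shape}"
            )
        return beats

    def _check(self, beats: np.ndarray) -> np.ndarray:
        """Validate and standardise; called exactly once, inside forward."""
        beats = self._validate(beats)
        if np.any(self.input_offset != 0.0) or np.any(self.input_scale != 1.0):
            beats = (beats - self.input_offset[None, :, None]) * (
                self.input_scale[None, :, None]
            )
        return beats

    def front_output(self, beats: np.ndarray) -> np.ndarray:
        """Bidirectional front-end sequence output (n, 325, 2·hidden)."""
        x = self._check(beats).transpose(0, 2, 1)  # (n, T, k)
        return np.concatenate(
            [self.front_f.forward(x, False), self.front_b.forward(x, False)], axis=-1
        )

    def forward(self, beats: np.ndarray, train: bool = False) -> np.ndarray:
        c = self.cfg
        x = self._check(beats).transpose(0, 2, 1)
        F = np.concatenate(
            [self.front_f.forward(x, train), self.front_b.forward(x, train)], axis=-1
        )
        X = F
        for b in self.blocks:
            A = b["prev"].forward(X, train)
            B = b["orig"].forward(F, train)
            C = b["comb_prev"].forward(A, train) + b["comb_orig"].forward(B, train)
            X = C + X if c.use_shortcut else C
        z = X[:, -1, :] if c.pool == "last" else X.mean(axis=1)
        self._pooled_T = X.shape[1]
        z = self.fc1.forward(z, train)
        if train and c.dropout > 0:
            self._mask = (
                self._drop_rng.random(z.shape) >= c.dropout
            ).astype(np.float32) / (1 - c.dropout)
            z = z * self._mask
        else:
            self._mask = None
        return self.fc2.forward(z, train)

    def _backward(self, dy: np.ndarray) -> None:
        c = self.cfg
        dz = self.fc2.backward(dy)
        if self._mask is not None:
            dz = dz * self._mask
        dz = self.fc1.backward(dz)
        n, T = dz.shape[0], self._pooled_T
        dX = np.zeros((n, T, dz.shape[-1]), dtype=np.float32)
        if c.pool == "last":
            dX[:, -1, :] = dz
        else:
            dX += dz[:, None, :] / T
        dF = np.zeros_like(dX)
        for b in reversed(self.blocks):
            dC = dX
            dA = b["comb_prev"].backward(dC)
            dB = b["comb_orig"].backward(dC)
            dF += b["orig"].backward(dB)
            dX = b["prev"].backward(dA)
            if c.use_shortcut:
                dX = dX + dC
        dF += dX
        h = c.hidden
        dxf = self.front_f.backward(dF[..., :h])
        dxb = self.front_b.backward(dF[..., h:])
        # gradient w.r.t. the input beats is not needed further
        _ = dxf + dxb

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {
            f"p{i}_{k}": v
            for i, lay in enumerate(self.layers)
            for k, v in lay.params.items()
        }
        meta = dict(kind="resbitime", k=self.k, num_classes=self.num_classes,
                    cfg=self.cfg.__dict__)
        np.savez(path, __config__=json.dumps(meta),
                 __input_offset__=self.input_offset,
                 __input_scale__=self.input_scale, **arrays)

    @classmethod
    def load(cls, path: str) -> "ResBiTimeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__config__"]))
            if meta.pop("kind") != "resbitime":
                raise ValueError("not a ResBiTime checkpoint")
            model = cls(meta["k"], meta["num_classes"], ResBiTimeConfig(**meta["cfg"]))
            model.input_offset = z["__input_offset__"]
            model.input_scale = z["__input_scale__"]
            for i, lay in enumerate(model.layers):
                for k in lay.params:
                    lay.params[k] = z[f"p{i}_{k}"]
        return model


def build_resbitime(
    k: int, num_classes: int = 9, cfg: ResBiTimeConfig | None = None
) -> ResBiTimeModel:
    return ResBiTimeModel(k, num_classes, cfg)


def slice_leads(bs: BeatSet, leads: list[str]) -> np.ndarray:
    """Restrict a BeatSet's beats to the named leads, in the given order."""
    idx = [lead_index(n) for n in leads]
    return bs.beats[:, idx, :]


def train_resbitime(
    model: ResBiTimeModel, beats: np.ndarray, labels: np.ndarray,
    cfg: ResBiTimeConfig | None = None,
) -> tuple[ResBiTimeModel, list[float]]:
    """Cross-entropy / Adam training on lead-sliced beats (n, k, 325).

    ``labels`` are integer class indices. Dropout is active only here;
    deterministic under the config seed.
    """
    cfg = cfg or model.cfg
    raw = np.asarray(beats, dtype=np.float32)
    if len(raw) == 0:
        raise ValueError("empty training set")
    if cfg.standardize_inputs and raw.ndim == 3:
        model.input_offset = raw.mean(axis=(0, 2)).astype(np.float32)
        sd = raw.std(axis=(0, 2)).astype(np.float32)
        model.input_scale = 1.0 / np.maximum(sd, 1e-6)
    # keep raw beats here: forward() standardises via _check exactly once
    beats = model._validate(raw)
    y = np.asarray(labels, dtype=np.int64)
    if len(y) != len(beats):
        raise ValueError("labels length must match beats")
    rng = np.random.default_rng(cfg.seed)
    steps = -(-len(beats) // cfg.batch_size) * cfg.epochs
    opt = Adam(
        model.layers,
        lr=cfg.lr,
        clip_norm=cfg.clip_norm,
        warmup_steps=int(cfg.warmup_frac * steps),
    )
    trace: list[float] = []
    n = len(beats)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(beats[idx], train=True)
            loss, dy = cross_entropy(logits, y[idx])
            if cfg.lr != 0.0:
                model._backward(dy)
                opt.step()
            losses.append(loss * len(idx))
        trace.append(float(np.sum(losses) / n))
    return model, trace


def predict(model: ResBiTimeModel, beats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax) and softmax score matrix; dropout disabled."""
    beats = model._validate(beats)
    scores = np.concatenate(
        [
            softmax(model.forward(beats[i : i + 256], train=False))
            for i in range(0, len(beats), 256)
        ]
    ) if len(beats) else np.empty((0, model.num_classes))
    return scores.argmax(axis=1), scores
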