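"""Lead-wise convolutional encoder for class-activation lead attribution.

A 1-D CNN over 12×325 heartbeats in which every convolution is *grouped by
lead*: lead c's features are computed from lead c alone, so nothing mixes
leads before the linear head. Global average pooling (GAP) collapses the
final 60 feature maps per lead to one scalar each, making the class score

    y_s = Σ_c Σ_k w_c^{k,s} · H_c^k + b_s

an affine function of per-lead pooled features H_c^k. That is what lets the
class evidence be decomposed exactly into per-lead activations
A_c^s = Σ_k w_c^{k,s} H_c^k (see :mod:`ecgleads.heatmap`).

Architecture (per lead; input 1×325):

====== ========== ============= ======
stage  kernels    kernel/stride length
====== ========== ============= ======
conv1  12         2 / 1         325
conv2  12         1 / 1         325
conv3  24         24 / 2        163
pool   —          3 / 1         163
conv4  24         1 / 1         163
conv5  32         32 / 1        163
pool   —          3 / 1         163
conv6  32         1 / 1         163
conv7  48         32 / 1        163
pool   —          3 / 1         163
conv8  48         1 / 1         163
conv9  60         48 / 1        163
pool   —          3 / 1         163
GAP    —          —             1
====== ========== ============= ======

followed by a single linear head 12·60 → 9. Every conv is ReLU-activated,
Kaiming-initialised and bias-free (the convolution is defined as h = x ∗ W);
the head carries the per-class bias. Nine conv stages, four pooling stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import BEAT_LEN, N_LEADS, BeatSet
from .nn import Adam, Conv1dGrouped, Linear, MaxPool1dSame, cross_entropy
from .nn.optim import SGD

#: (c_in, c_out, kernel, stride, pool_after) per conv stage.
_STAGES = (
    (1, 12, 2, 1, False),
    (12, 12, 1, 1, False),
    (12, 24, 24, 2, True),
    (24, 24, 1, 1, False),
    (24, 32, 32, 1, True),
    (32, 32, 1, 1, False),
    (32, 48, 32, 1, True),
    (48, 48, 1, 1, False),
    (48, 60, 48, 1, True),
)

FEATS_PER_LEAD = 60
FINAL_LEN = 163


@dataclass
class TrainConfig:
    """Optimisation settings (defaults are the encoder's published recipe).

    ``center_inputs`` subtracts the training-set mean beat (one 325-sample
    template per lead, stored on the model and applied at every forward
    pass), so the network sees morphology *deviations* rather than the large
    class-independent P-QRS-T waveform; ``scale_inputs`` then divides each
    lead by the residual's standard deviation. Both are lead-local, so the
    attribution contracts (lead locality, activation decomposition) are
    unaffected; an untrained model has offset 0 and gain 1.
    """

    batch_size: int = 32
    epochs: int = 60
    lr: float = 5e-4
    seed: int = 0
    center_inputs: bool = True
    scale_inputs: bool = True
    warmup_frac: float = 0.2  # fraction of total steps under linear lr warmup
    adam_eps: float = 1e-8
    optimizer: str = "adam"  # "adam" | "sgd" (momentum 0.9)
    #: decoupled L2 decay on the linear head per step; shrinks readout
    #: weights that receive no consistent gradient (uninformative leads)
    head_decay: float = 0.0
    #: Polyak/EMA decay for the returned weights (0 disables).
    ema_decay: float = 0.0
    #: probability of dropping a whole lead's pooled features per training
    #: step; forces the head to spread evidence over all informative leads
    #: instead of co-adapting to a sufficient subset
    lead_dropout: float = 0.3


@dataclass
class FeatureMaps:
    """Forward-pass artefacts for a batch of beats.

    h — final per-lead feature maps (n, 12, 60, 163), after the last pooling
    stage; H — their temporal mean (n, 12, 60); y — class scores (n, 9).
    """

    h: np.ndarray
    H: np.ndarray
    y: np.ndarray


class LeadWiseModel:
    """The grouped CNN plus its linear head."""

    def __init__(
        self,
        num_leads: int = N_LEADS,
        num_classes: int = 9,
        seed: int = 0,
        shared_leads: bool = False,
    ) -> None:
        if num_leads < 1 or num_classes < 2:
            raise ValueError("need num_leads ≥ 1 and num_classes ≥ 2")
        self.num_leads, self.num_classes = num_leads, num_classes
        self.seed, self.shared_leads = seed, shared_leads
        rng = np.random.default_rng(seed)
        #: per-lead input gain (1/std of the training data when scaled)
        self.input_scale = np.ones(num_leads, dtype=np.float32)
        #: per-lead mean-beat template removed from every input when centred
        self.input_offset = np.zeros((num_leads, BEAT_LEN), dtype=np.float32)
        #: training-time lead-dropout probability (set by train_leadwise)
        self.lead_dropout = 0.0
        self._drop_rng = np.random.default_rng(seed + 1)
        self._lead_mask = None
        self.stack: list = []
        for c_in, c_out, k, s, pool in _STAGES:
            conv = Conv1dGrouped(num_leads, c_in, c_out, k, s, rng=rng)
            if shared_leads:
                for key in conv.params:
                    conv.params[key][:] = conv.params[key][0]
            self.stack.append(conv)
            if pool:
                self.stack.append(MaxPool1dSame(3))
        self.head = Linear(num_leads * FEATS_PER_LEAD, num_classes, rng=rng)

    # -- introspection used by the architecture contract ---------------------
    @property
    def n_conv_stages(self) -> int:
        return sum(isinstance(l, Conv1dGrouped) for l in self.stack)

    @property
    def n_pool_stages(self) -> int:
        return sum(isinstance(l, MaxPool1dSame) for l in self.stack)

    def head_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Head as (leads, feats, classes) weight tensor and (classes,) bias."""
        W = self.head.params["W"].reshape(
            self.num_leads, FEATS_PER_LEAD, self.num_classes
        )
        return W, self.head.params["b"]

    # -- forward / backward --------------------------------------------------
    def _check(self, beats: np.ndarray) -> np.ndarray:
        beats = np.asarray(beats, dtype=np.float32)
        if beats.ndim == 2:
            beats = beats[None]
        if beats.shape[1:] != (self.num_leads, BEAT_LEN):
            raise ValueError(
                f"beats must be n×{self.num_leads}×{BEAT_LEN}, got {beats.shape}"
            )
        return beats

    def forward(self, beats: np.ndarray, train: bool = False) -> FeatureMaps:
        x = self._check(beats)
        if np.any(self.input_offset != 0.0):
            x = x - self.input_offset[None]
        if not np.all(self.input_scale == 1.0):
            x = x * self.input_scale[None, :, None]
        x = x[:, :, :, None]  # (n, leads, 325, 1) channels-last
        for layer in self.stack:
            x = layer.forward(x, train=train)
        self._h_len = x.shape[2]
        H = x.mean(axis=2)  # (n, leads, 60)
        h = x.transpose(0, 1, 3, 2)  # (n, leads, 60, time)
        H_in = H
        self._lead_mask = None
        if train and self.lead_dropout > 0.0:
            keep = (
                self._drop_rng.random((len(H), self.num_leads, 1))
                >= self.lead_dropout
            ).astype(np.float32) / (1.0 - self.lead_dropout)
            self._lead_mask = keep
            H_in = H * keep
        y = self.head.forward(H_in.reshape(len(H), -1), train=train)
        return FeatureMaps(h=h, H=H, y=y)

    def _backward(self, dy: np.ndarray) -> None:
        dH = self.head.backward(dy)
        dH = dH.reshape(len(dH), self.num_leads, FEATS_PER_LEAD)
        if self._lead_mask is not None:
            dH = dH * self._lead_mask
        T = self._h_len
        g = np.broadcast_to(
            dH.reshape(len(dH), self.num_leads, 1, FEATS_PER_LEAD) / T,
            (len(dH), self.num_leads, T, FEATS_PER_LEAD),
        ).astype(np.float32)
        for layer in reversed(self.stack):
            g = layer.backward(g)

    @property
    def layers(self) -> list:
        return [*self.stack, self.head]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {
            f"p{i}_{k}": v
            for i, lay in enumerate(self.layers)
            for k, v in lay.params.items()
        }
        meta = dict(
            kind="leadwise",
            num_leads=self.num_leads,
            num_classes=self.num_classes,
            seed=self.seed,
            shared_leads=self.shared_leads,
        )
        np.savez(
            path, __config__=json.dumps(meta), __input_scale__=self.input_scale,
            __input_offset__=self.input_offset, **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "LeadWiseModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__config__"]))
            if meta.pop("kind") != "leadwise":
                raise ValueError("not a lead-wise model checkpoint")
            model = cls(**meta)
            model.input_scale = z["__input_scale__"]
            model.input_offset = z["__input_offset__"]
            for i, lay in enumerate(model.layers):
                for k in lay.params:
                    lay.params[k] = z[f"p{i}_{k}"]
        return model


def build_leadwise(
    num_leads: int = N_LEADS,
    num_classes: int = 9,
    seed: int = 0,
    shared_leads: bool = False,
) -> LeadWiseModel:
    return LeadWiseModel(num_leads, num_classes, seed, shared_leads)


def forward_leadwise(model: LeadWiseModel, beats: np.ndarray) -> FeatureMaps:
    """Batched inference returning feature maps, pooled features and scores."""
    return model.forward(beats, train=False)


def train_leadwise(
    model: LeadWiseModel, train: BeatSet, cfg: TrainConfig = TrainConfig()
) -> tuple[LeadWiseModel, list[float]]:
    """Cross-entropy training with Adam; returns the model and per-epoch loss."""
    if len(train) == 0:
        raise ValueError("empty training set")
    y = train.encoded_labels()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    if cfg.center_inputs:
        model.input_offset = train.beats.mean(axis=0).astype(np.float32)
    if cfg.scale_inputs:
        resid = train.beats - model.input_offset[None]
        sd = resid.std(axis=(0, 2)).astype(np.float32)
        model.input_scale = 1.0 / np.maximum(sd, 1e-6)
    rng = np.random.default_rng(cfg.seed)
    n = len(train)
    steps_per_epoch = -(-n // cfg.batch_size)
    warmup = int(cfg.warmup_frac * cfg.epochs * steps_per_epoch)
    if cfg.optimizer == "sgd":
        opt = SGD(model.layers, lr=cfg.lr, warmup_steps=warmup)
    else:
        opt = Adam(model.layers, lr=cfg.lr, warmup_steps=warmup, eps=cfg.adam_eps)
    model.lead_dropout = cfg.lead_dropout
    model._drop_rng = np.random.default_rng(cfg.seed + 1)
    ema = None
    if cfg.ema_decay:
        ema = [
            {k: v.copy() for k, v in lay.params.items()} for lay in model.layers
        ]
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            fm = model.forward(train.beats[idx], train=True)
            loss, dy = cross_entropy(fm.y, y[idx])
            if cfg.lr != 0.0:
                model._backward(dy)
                opt.step()
                if cfg.head_decay:
                    model.head.params["W"] *= 1.0 - cfg.lr * cfg.head_decay
                if ema is not None:
                    d = cfg.ema_decay
                    for lay, e in zip(model.layers, ema):
                        for k, v in lay.params.items():
                            e[k] = d * e[k] + (1.0 - d) * v
            losses.append(loss * len(idx))
        trace.append(float(np.sum(losses) / n))
    if ema is not None and cfg.lr != 0.0:
        for lay, e in zip(model.layers, ema):
            for k in lay.params:
                lay.params[k] = e[k]
    return model, trace
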