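"""Lead activation (LA) heatmaps and lead selection.

Because the lead-wise encoder never mixes leads before its GAP + linear head,
the class score decomposes exactly as y_s = Σ_c A_c^s + b_s with

    A_c^s = Σ_k w_c^{k,s} H_c^k,

the weighted sum of lead c's pooled features under class s's head weights.
Averaging A over all beats of each true class and min–max normalising each
class across the 12 leads gives the LA heatmap: a leads × classes matrix in
[0, 1] showing which leads carry the evidence for each rhythm class. Leads
are ranked by their mean normalised activation across classes; the top k
(default 5) are kept for the downstream classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CLASS_NAMES, LEAD_NAMES, BeatSet
from .leadwise import LeadWiseModel, forward_leadwise


@dataclass
class LeadActivation:
    """Per-beat decomposition: A is leads × classes; bias the head bias."""

    A: np.ndarray
    bias: np.ndarray


@dataclass
class LAHeatmap:
    """Aggregated, per-class min–max normalised activations (leads × classes)."""

    M: np.ndarray
    lead_names: tuple[str, ...] = LEAD_NAMES
    class_names: tuple[str, ...] = CLASS_NAMES
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.shape != (len(self.lead_names), len(self.class_names)):
            raise ValueError(
                f"heatmap must be {len(self.lead_names)}×{len(self.class_names)}, "
                f"got {self.M.shape}"
            )
        if not np.all(np.isfinite(self.M)):
            raise ValueError("heatmap contains non-finite entries")


def _activations(model: LeadWiseModel, beats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw A (n, leads, classes) and bias for a batch of beats.

    The forward pass is chunked so large aggregation sets keep a small
    memory footprint.
    """
    W, b = model.head_weights()  # (leads, feats, classes), (classes,)
    beats = np.asarray(beats)
    if beats.ndim == 2:
        beats = beats[None]
    chunks = []
    for i in range(0, len(beats), 64):
        H = forward_leadwise(model, beats[i : i + 64]).H
        chunks.append(
            np.einsum("nlf,lfs->nls", H.astype(np.float64), W.astype(np.float64))
        )
    return np.concatenate(chunks), b.astype(np.float64)


def lead_activation(model: LeadWiseModel, beat: np.ndarray) -> LeadActivation:
    """Exact per-lead class-activation decomposition of one beat."""
    A, b = _activations(model, np.asarray(beat)[None] if np.asarray(beat).ndim == 2 else beat)
    return LeadActivation(A=A[0], bias=b)


def _normalize_per_class(A: np.ndarray) -> np.ndarray:
    """Min–max each class (column) across leads to [0, 1]; flat columns → 0."""
    lo = A.min(axis=0, keepdims=True)
    hi = A.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(A)
    np.divide(A - lo, span, out=out, where=span > 0)
    return out


def aggregate_heatmap(model: LeadWiseModel, bs: BeatSet) -> LAHeatmap:
    """Fig.-4-style heatmap: mean activation per true class, then normalised.

    Classes absent from ``bs`` get an all-zero column (a warning is sensible
    upstream; selection still works on the remaining classes).
    """
    if len(bs) == 0:
        raise ValueError("cannot aggregate an empty BeatSet")
    A, _ = _activations(model, bs.beats)
    y = bs.encoded_labels()
    overall = A.mean(axis=0)  # fallback for classes absent from bs
    mean_A = np.zeros((len(LEAD_NAMES), len(CLASS_NAMES)))
    missing = []
    for s in range(len(CLASS_NAMES)):
        mask = y == s
        if mask.any():
            mean_A[:, s] = A[mask, :, s].mean(axis=0)
        else:
            mean_A[:, s] = overall[:, s]
            missing.append(CLASS_NAMES[s])
    if missing:
        warnings.warn(
            f"classes absent from BeatSet, using all-beat mean activation: {missing}",
            stacklevel=2,
        )
    return LAHeatmap(_normalize_per_class(mean_A), n_samples=len(bs))


def per_sample_heatmap(model: LeadWiseModel, beat: np.ndarray) -> LAHeatmap:
    """Single-beat heatmap (all 9 class columns, normalised per class)."""
    la = lead_activation(model, beat)
    return LAHeatmap(_normalize_per_class(la.A), n_samples=1)


def select_leads(hm: LAHeatmap, k: int = 5) -> list[str]:
    """Top-k leads by mean normalised activation across classes.

    Deterministic: ties are broken in favour of the canonical lead order; the
    result is ordered by decreasing score. Scale-invariant by construction
    (normalisation removes any positive global factor).
    """
    if not 1 <= k <= len(hm.lead_names):
        raise ValueError(f"k must be in [1, {len(hm.lead_names)}]")
    scores = hm.M.mean(axis=1)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [hm.lead_names[i] for i in order[:k]]


def lead_scores(hm: LAHeatmap) -> dict[str, float]:
    """Mean normalised activation per lead (the selection ranking scores)."""
    return {n: float(s) for n, s in zip(hm.lead_names, hm.M.mean(axis=1))}
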