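"""Signal conditioning and beat extraction.

The pipeline mirrors standard clinical-ECG practice at 500 Hz:

1.  **Wavelet denoising** — 9-level db6 decomposition; the three finest detail
    bands D1–D3 (≈31–250 Hz: EMG and 50 Hz power-line interference) and the
    level-9 approximation A9 (≈0–0.5 Hz: baseline wander) are zeroed before
    reconstruction. Retaining D4–D9 equals "A8 with its A9 part removed", so
    the band-set honours both the 9-level decomposition and the removal list.
2.  **R-peak detection** — the Pan–Tompkins chain (5–15 Hz band-pass,
    five-point derivative, squaring, 150 ms moving-window integration,
    adaptive dual thresholds with a 200 ms refractory period and search-back),
    followed by refinement of each fiducial to the local signal maximum within
    ±50 ms.
3.  **Segmentation** — 125 samples left and 199 right of each R peak, giving
    325-sample beats with the R apex at within-beat index 125.
4.  **Split / balance** — stratified 80/20 split per class; training classes
    below a count threshold are replicated whole (original block repeated) so
    minority classes reach factor × their original size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core import BEAT_LEN, BEAT_POST, BEAT_PRE, CLASS_NAMES, MULTI_LABEL, BeatSet, EcgRecord

_WAVELET = "db6"
_LEVELS = 9
_REMOVE_DETAILS = (1, 2, 3)  # D1..D3


class SignalTooShortError(ValueError):
    pass


def denoise_dwt(
    signal: np.ndarray,
    fs: float = 500.0,
    *,
    remove_details: tuple[int, ...] = _REMOVE_DETAILS,
    remove_approx: bool = True,
) -> np.ndarray:
    """Denoise one lead by db6 wavelet band removal.

    Removes detail levels ``remove_details`` and (optionally) the level-9
    approximation, then reconstructs to the original length. With an empty
    removal set this is a perfect-reconstruction round trip. Symmetric signal
    extension is used at the boundaries.

    At fs = 500 Hz the removed defaults map to ≈31–250 Hz (D1–D3) and
    ≈0–0.5 Hz (A9); other rates are accepted but the band edges scale with fs.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("denoise_dwt expects a single lead (1-D array)")
    if len(x) < 2**_LEVELS:
        raise SignalTooShortError(
            f"signal of length {len(x)} is too short for a {_LEVELS}-level "
            "db6 decomposition; use a longer signal or fewer levels"
        )
    with warnings.catch_warnings():
        # pywt warns when level exceeds its conservative recommendation
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, _WAVELET, level=_LEVELS, mode="symmetric")
    # coeffs = [A9, D9, D8, ..., D1]
    if remove_approx:
        coeffs[0] = np.zeros_like(coeffs[0])
    for d in remove_details:
        coeffs[-d] = np.zeros_like(coeffs[-d])
    rec = pywt.waverec(coeffs, _WAVELET, mode="symmetric")
    return rec[: len(x)]


def denoise_record(record: EcgRecord) -> EcgRecord:
    """Apply :func:`denoise_dwt` independently to each of the 12 leads."""
    clean = np.vstack([denoise_dwt(row, record.fs) for row in record.signal])
    return EcgRecord(record.record_id, clean, record.fs, record.label)


@dataclass
class RPeakList:
    """Detected R-peak sample positions (0-based, strictly increasing)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


def detect_r_peaks(lead_signal: np.ndarray, fs: float = 500.0) -> RPeakList:
    """Pan–Tompkins QRS detection on one (denoised) lead.

    Flat or near-flat signals yield an empty list rather than an error.
    """
    x = np.asarray(lead_signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("detect_r_peaks expects a 1-D lead signal")
    if len(x) < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    if np.ptp(x) < 1e-12:
        return RPeakList(np.empty(0, dtype=np.int64), fs)

    sos = butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    # Five-point derivative (1/8)(-x[n-2] - 2x[n-1] + 2x[n+1] + x[n+2]).
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) / 8.0, mode="same")
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # Candidate local maxima of the integrated signal; keeping only the
    # largest peak inside each refractory span suppresses filter ripple.
    cand, _ = find_peaks(mwi, distance=refractory)

    spki = float(np.max(mwi[: int(2 * fs)])) * 0.25  # running signal-peak level
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5  # running noise-peak level
    peaks: list[int] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        if peaks and c - peaks[-1] < refractory:
            continue
        if mwi[c] > threshold():
            peaks.append(int(c))
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki

    # Search-back: re-scan long RR gaps at half threshold.
    if len(peaks) >= 2:
        rr = np.diff(peaks)
        mean_rr = float(np.mean(rr))
        extra: list[int] = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            if b - a > 1.66 * mean_rr:
                seg = cand[(cand > a + refractory) & (cand < b - refractory)]
                if seg.size:
                    best = seg[np.argmax(mwi[seg])]
                    if mwi[best] > 0.5 * threshold():
                        extra.append(int(best))
        peaks = sorted(set(peaks) | set(extra))

    # Refine each fiducial to the local raw-signal maximum within ±50 ms.
    half = int(round(0.050 * fs))
    refined: list[int] = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        r = lo + int(np.argmax(x[lo:hi]))
        if not refined or r - refined[-1] >= refractory:
            refined.append(r)
    return RPeakList(np.asarray(refined, dtype=np.int64), fs)


def segment_beats(record: EcgRecord, peaks: RPeakList) -> BeatSet:
    """Cut 12×325 beats around each interior R peak.

    A peak r is kept only if the full window [r−125, r+199] lies inside the
    record; boundary peaks are silently dropped. Every beat inherits the
    record's label, so records flagged "multi" must be filtered upstream.
    """
    if record.label == MULTI_LABEL:
        raise ValueError(
            f"record {record.record_id!r} has multiple labels; "
            "filter multi-label records before segmentation"
        )
    T = record.n_samples
    keep = [
        int(r)
        for r in peaks.indices
        if r - BEAT_PRE >= 0 and r + BEAT_POST <= T - 1
    ]
    beats = np.stack(
        [record.signal[:, r - BEAT_PRE : r + BEAT_POST + 1] for r in keep]
    ).astype(np.float32) if keep else np.empty((0, 12, BEAT_LEN), np.float32)
    labels = np.array([record.label] * len(keep))
    prov = np.array([record.record_id] * len(keep))
    return BeatSet(beats, labels, "train", prov)


def split_dataset(
    bs: BeatSet, train_frac: float = 0.8, seed: int = 0
) -> tuple[BeatSet, BeatSet]:
    """Stratified random split; train gets round(train_frac·n) per class.

    Rounding is banker's (round-half-even). Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in CLASS_NAMES:
        idx = np.flatnonzero(bs.labels == c)
        if idx.size == 0:
            continue
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 beats; cannot split")
        perm = rng.permutation(idx)
        n_train = round(train_frac * idx.size)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx)) if train_idx else np.empty(0, int)
    te = np.sort(np.concatenate(test_idx)) if test_idx else np.empty(0, int)
    return bs.subset(tr, "train"), bs.subset(te, "test")


@dataclass(frozen=True)
class BalanceRule:
    """Duplicate any training class below ``threshold`` to factor × its size."""

    threshold: int = 8000
    factor: int = 3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.factor < 1:
            raise ValueError("factor must be ≥ 1")


def balanced_counts(counts: dict[str, int], rule: BalanceRule) -> dict[str, int]:
    """Post-balancing per-class counts under ``rule`` (count-level arithmetic)."""
    return {
        c: n * rule.factor if n < rule.threshold else n for c, n in counts.items()
    }


def balance_training(train: BeatSet, rule: BalanceRule = BalanceRule()) -> BeatSet:
    """Oversample minority training classes by whole-block duplication.

    Classes with fewer than ``rule.threshold`` beats are repeated so they end
    at factor × original (original block followed by factor−1 copies, in the
    original order); the rest pass through untouched. Never apply to a test
    split.
    """
    if train.split_tag != "train":
        raise ValueError("balance_training must only be applied to a train split")
    parts_b, parts_l, parts_p = [], [], []
    for c in CLASS_NAMES:
        idx = np.flatnonzero(train.labels == c)
        if idx.size == 0:
            continue
        reps = rule.factor if idx.size < rule.threshold else 1
        for _ in range(reps):
            parts_b.append(train.beats[idx])
            parts_l.append(train.labels[idx])
            parts_p.append(train.provenance[idx])
    if not parts_b:
        return train
    return BeatSet(
        np.concatenate(parts_b),
        np.concatenate(parts_l),
        "train",
        np.concatenate(parts_p),
    )
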