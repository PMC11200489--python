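"""Core domain types for 12-lead ECG heartbeat analysis.

The package works with standard 12-lead clinical ECGs sampled at 500 Hz.
Two containers travel through the whole pipeline:

* :class:`EcgRecord` — one multi-lead recording (12 × T samples, mV) with a
  single rhythm-class label, or the ``"multi"`` sentinel for recordings whose
  reference sheet carries more than one label (those never contribute beats).
* :class:`BeatSet` — a stack of segmented heartbeats, each 12 × 325 samples
  with the R-wave apex at within-beat index 125, plus per-beat labels and the
  provenance record IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical 12-lead order used everywhere (rows of signals, heatmaps, ...).
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Fixed 9-class rhythm-label order (confusion matrices, heatmap columns).
CLASS_NAMES: tuple[str, ...] = (
    "N", "AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC", "STD", "STE",
)

#: Sentinel label for records whose reference sheet lists multiple rhythms.
MULTI_LABEL = "multi"

#: Samples kept left of the R apex, right of it, and the resulting beat length.
BEAT_PRE = 125
BEAT_POST = 199
BEAT_LEN = BEAT_PRE + BEAT_POST + 1  # 325

N_LEADS = 12
DEFAULT_FS = 500.0


def lead_index(name: str) -> int:
    """Position of a lead name in the canonical order."""
    try:
        return LEAD_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown lead name: {name!r}") from None


def class_index(code: str) -> int:
    try:
        return CLASS_NAMES.index(code)
    except ValueError:
        raise KeyError(f"unknown class code: {code!r}") from None


@dataclass
class EcgRecord:
    """One 12-lead recording: ``signal`` is leads × time in millivolts."""

    record_id: str
    signal: np.ndarray
    fs: float = DEFAULT_FS
    label: str = MULTI_LABEL

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_LEADS:
            raise ValueError(
                f"record {self.record_id!r}: signal must be {N_LEADS}×T, "
                f"got shape {self.signal.shape}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.label != MULTI_LABEL and self.label not in CLASS_NAMES:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BeatSet:
    """A labelled stack of segmented heartbeats (n × 12 × 325, mV)."""

    beats: np.ndarray
    labels: np.ndarray
    split_tag: str = "train"
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=np.float32)
        if self.beats.size == 0:
            self.beats = self.beats.reshape(0, N_LEADS, BEAT_LEN)
        if self.beats.ndim != 3 or self.beats.shape[1:] != (N_LEADS, BEAT_LEN):
            raise ValueError(
                f"beats must be n×{N_LEADS}×{BEAT_LEN}, got {self.beats.shape}"
            )
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.provenance is None:
            self.provenance = np.array([""] * len(self.labels), dtype="U64")
        self.provenance = np.asarray(self.provenance, dtype="U64")
        n = self.beats.shape[0]
        if len(self.labels) != n or len(self.provenance) != n:
            raise ValueError("labels/provenance length must match beat count")
        bad = set(np.unique(self.labels)) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"labels outside the 9-class set: {sorted(bad)}")
        if self.split_tag not in ("train", "test"):
            raise ValueError("split_tag must be 'train' or 'test'")

    def __len__(self) -> int:
        return self.beats.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASS_NAMES}

    def subset(self, idx: np.ndarray, split_tag: str | None = None) -> "BeatSet":
        return BeatSet(
            self.beats[idx],
            self.labels[idx],
            split_tag or self.split_tag,
            self.provenance[idx],
        )

    def encoded_labels(self) -> np.ndarray:
        """Labels as integer class indices in the canonical order."""
        return np.array([class_index(c) for c in self.labels], dtype=np.int64)
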