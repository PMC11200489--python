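"""Readers and writers for the pipeline's file formats.

* **Records** — per-record MAT files holding one 12×T (or T×12,
  auto-transposed) numeric matrix in mV, plus a CSV reference sheet mapping
  record IDs to rhythm labels. A sheet row with more than one non-empty label
  field marks the record ``"multi"``; such records are excluded downstream.
* **Beat sets** — HDF5 containers with beats (n×12×325 float32), labels,
  provenance and the split tag. Datasets are written with ``track_times``
  off so identical content yields byte-identical files.
* **Heatmaps** — CSV, lead names down the first column, class codes across
  the header. **Metrics** — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .core import (
    BEAT_LEN,
    CLASS_NAMES,
    MULTI_LABEL,
    N_LEADS,
    BeatSet,
    EcgRecord,
)
from .heatmap import LAHeatmap


# ---------------------------------------------------------------- label sheet
def read_label_sheet(path: str | Path) -> dict[str, str]:
    """Map record ID → class code, or ``"multi"`` for multi-label rows.

    The first column is the record ID; every remaining column is treated as a
    potential label field, so any sheet layout with one-or-more label columns
    works.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        rid = str(row.iloc[0]).strip()
        labels = [v.strip() for v in row.iloc[1:] if str(v).strip()]
        if not rid:
            continue
        if len(labels) > 1:
            out[rid] = MULTI_LABEL
        elif len(labels) == 1:
            if labels[0] not in CLASS_NAMES:
                raise ValueError(
                    f"record {rid!r}: unknown class code {labels[0]!r}"
                )
            out[rid] = labels[0]
        else:
            raise ValueError(f"record {rid!r} has no label")
    return out


# -------------------------------------------------------------------- records
def read_record(path: str | Path, label_sheet: dict[str, str]) -> EcgRecord:
    """Load one MAT record and attach its label from the reference sheet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rid = path.stem
    if rid not in label_sheet:
        raise KeyError(f"record {rid!r} absent from the label sheet")
    mat = loadmat(path)
    arrays = [
        np.asarray(v)
        for k, v in mat.items()
        if not k.startswith("__") and np.asarray(v).ndim == 2
    ]
    mats = [a for a in arrays if N_LEADS in a.shape]
    if not mats:
        raise ValueError(f"{path}: no matrix with a {N_LEADS}-sized axis")
    sig = mats[0].astype(np.float64)
    if sig.shape[0] == N_LEADS and sig.shape[1] == N_LEADS:
        raise ValueError(f"{path}: both axes are {N_LEADS}; orientation ambiguous")
    if sig.shape[0] != N_LEADS:
        sig = sig.T
    return EcgRecord(rid, sig, label=label_sheet[rid])


def write_record(record: EcgRecord, path: str | Path) -> None:
    """Persist a record as a MAT file (leads × time matrix under ``val``)."""
    savemat(Path(path), {"val": record.signal})


# ------------------------------------------------------------------ beat sets
def write_beatset(bs: BeatSet, path: str | Path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("beats", data=bs.beats, track_times=False)
        f.create_dataset(
            "labels", data=bs.labels.astype("S8"), track_times=False
        )
        f.create_dataset(
            "provenance", data=bs.provenance.astype("S64"), track_times=False
        )
        f.attrs["split_tag"] = bs.split_tag


def read_beatset(path: str | Path) -> BeatSet:
    with h5py.File(path, "r") as f:
        beats = f["beats"][()]
        if beats.ndim != 3 or beats.shape[1:] != (N_LEADS, BEAT_LEN):
            raise ValueError(
                f"{path}: beats must be n×{N_LEADS}×{BEAT_LEN}, got {beats.shape}"
            )
        return BeatSet(
            beats,
            f["labels"][()].astype("U8"),
            str(f.attrs["split_tag"]),
            f["provenance"][()].astype("U64"),
        )


# ------------------------------------------------------------------- heatmaps
def write_heatmap(hm: LAHeatmap, path: str | Path) -> None:
    df = pd.DataFrame(hm.M, index=list(hm.lead_names), columns=list(hm.class_names))
    df.index.name = "lead"
    df.to_csv(path, float_format="%.10g")


def read_heatmap(path: str | Path) -> LAHeatmap:
    df = pd.read_csv(path, index_col=0)
    return LAHeatmap(
        df.to_numpy(dtype=float),
        lead_names=tuple(df.index),
        class_names=tuple(df.columns),
    )


# -------------------------------------------------------------------- metrics
def write_metrics(metrics_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics_dict, indent=2) + "\n")


def read_predictions_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with ``true`` and ``predicted`` columns → two label arrays."""
    df = pd.read_csv(path, dtype=str)
    for col in ("true", "predicted"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df["true"].to_numpy(dtype="U8"), df["predicted"].to_numpy(dtype="U8")


def write_predictions_csv(
    path: str | Path,
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    scores: np.ndarray | None = None,
) -> None:
    data: dict = {"true": true_labels, "predicted": predicted_labels}
    if scores is not None:
        for j, c in enumerate(CLASS_NAMES):
            data[f"score_{c}"] = scores[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
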