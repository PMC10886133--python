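"""File I/O: raw-signal container files and delimited-text result tables.

Raw multimodal signals go into one HDF5 container per trial with named
datasets (``emg_<muscle>``, ``acc_<muscle>_<x|y|z>`` at the EMG rate,
``grf`` at half that) and trial metadata as attributes.  Everything
derived — feature matrices, confusion matrices, sweep tables, decision
streams — is written as tab-separated text so results stay greppable
and diffable; feature matrices carry a JSON sidecar with the windowing
and channel metadata needed to reload them.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FeatureMatrix, get_feature_set
from .synthetic import (CLASSES, LocomotionClass, MultimodalRecording)

_AXES = ("x", "y", "z")


def save_recording(rec: MultimodalRecording, path) -> None:
    """Write one trial to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for i, ch in enumerate(rec.channels):
            f.create_dataset(f"emg_{ch}", data=rec.emg[i])
            for j, ax in enumerate(_AXES):
                f.create_dataset(f"acc_{ch}_{ax}", data=rec.acc[i, j])
        f.create_dataset("grf", data=rec.grf)
        f.create_dataset("cycle_starts_truth", data=rec.cycle_starts_truth)
        f.attrs["label_id"] = rec.label.id
        f.attrs["label_name"] = rec.label.name
        f.attrs["emg_rate"] = rec.emg_rate
        f.attrs["grf_rate"] = rec.grf_rate
        f.attrs["channels"] = list(rec.channels)
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed


def load_recording(path) -> MultimodalRecording:
    """Read a trial previously written by :func:`save_recording`."""
    with h5py.File(path, "r") as f:
        channels = tuple(
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["channels"])
        emg = np.stack([f[f"emg_{ch}"][...] for ch in channels])
        acc = np.stack([
            np.stack([f[f"acc_{ch}_{ax}"][...] for ax in _AXES])
            for ch in channels])
        grf = f["grf"][...]
        starts = f["cycle_starts_truth"][...]
        label = _class_by_id(int(f.attrs["label_id"]))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return MultimodalRecording(
            emg=emg, acc=acc, grf=grf, label=label,
            cycle_starts_truth=starts,
            emg_rate=float(f.attrs["emg_rate"]),
            grf_rate=float(f.attrs["grf_rate"]),
            channels=channels, seed=seed)


def _class_by_id(cid: int) -> LocomotionClass:
    for c in CLASSES:
        if c.id == cid:
            return c
    raise ValueError(f"unknown class id {cid}")


def export_recording_csv(rec: MultimodalRecording, path) -> None:
    """Delimited-text export of one trial on the EMG timeline.

    GRF (half rate) is upsampled by sample-and-hold so all columns share
    one time base; intended for interoperability, not as the primary
    container.
    """
    cols = {}
    for i, ch in enumerate(rec.channels):
        cols[f"emg_{ch}"] = rec.emg[i]
        for j, ax in enumerate(_AXES):
            cols[f"acc_{ch}_{ax}"] = rec.acc[i, j]
    cols["grf"] = np.repeat(rec.grf, 2)[: rec.n_emg_samples]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def save_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """TSV with a header row plus a ``.meta.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.column_names)
    df.insert(0, "trial_id", matrix.trial_ids)
    df.insert(1, "cycle_id", matrix.cycle_ids)
    df.insert(2, "window_start", matrix.window_starts)
    df.insert(3, "label", matrix.labels)
    df.to_csv(path, sep="\t", index=False)
    meta = {"feature_set": matrix.spec.name,
            "channels": list(matrix.channels),
            "columns": list(matrix.column_names)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def load_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(
        path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path, sep="\t")
    spec = get_feature_set(meta["feature_set"])
    return FeatureMatrix(
        values=df[meta["columns"]].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        window_starts=df["window_start"].to_numpy(dtype=int),
        cycle_ids=df["cycle_id"].to_numpy(dtype=int),
        spec=spec, channels=tuple(meta["channels"]),
        trial_ids=df["trial_id"].to_numpy(dtype=int),
        column_names=list(meta["columns"]))


def save_confusion(cm, class_names, path) -> None:
    """Confusion counts as TSV, rows true / columns predicted."""
    names = [class_names[c] for c in cm.class_ids]
    df = pd.DataFrame(cm.counts, index=names, columns=names)
    df.index.name = "true\\pred"
    df.to_csv(path, sep="\t")


def save_table(rows: list[dict], path) -> None:
    """Generic result table writer (list of records -> TSV)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_decision_stream(stream, path, class_names=None,
                         torques=None) -> None:
    """Decision stream as TSV: time, window end, class, optional torque."""
    df = pd.DataFrame({
        "time_ms": stream.times_ms,
        "window_end_emg": stream.timestamps_emg,
        "cycle_id": stream.cycle_ids,
        "class_id": stream.predictions,
    })
    if class_names is not None:
        df["class_name"] = [class_names[c] for c in stream.predictions]
    if torques is not None:
        df["torque_Nm"] = torques
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
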