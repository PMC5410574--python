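"""Reading and writing recordings and ground truth.

Recordings travel as HDF5 (one dataset per channel with rate and
provenance attributes) or two-column CSV (time_s, mV); synthetic ground
truth as plain text (whitespace-separated truth tokens, two-column CSV of
truth times).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .detect import Recording

__all__ = ["save_recording", "load_recording", "load_recording_csv",
           "save_truth", "load_truth"]


def save_recording(rec: Recording, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=np.asarray(rec.samples, dtype=np.float32))
        d.attrs["rate_hz"] = float(rec.rate_hz)
        d.attrs["segment_id"] = rec.segment_id
        d.attrs["step_id"] = rec.step_id
        d.attrs["maneuver"] = rec.maneuver or ""


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["samples"]
        return Recording(segment_id=str(d.attrs["segment_id"]),
                         step_id=str(d.attrs["step_id"]),
                         samples=np.asarray(d[...], dtype=float),
                         rate_hz=float(d.attrs["rate_hz"]),
                         maneuver=str(d.attrs.get("maneuver", "")) or None)


def load_recording_csv(path, segment_id: str = "", step_id: str = "") -> Recording:
    """Two-column CSV (time_s, mV) on a uniform grid."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t)))
    return Recording(segment_id=segment_id, step_id=step_id,
                     samples=df.iloc[:, 1].to_numpy(dtype=float), rate_hz=rate)


def save_truth(tokens, times, stem) -> None:
    """Truth tokens as text; truth times as (time_s, label) CSV."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    stem.with_name(stem.name + ".truth_tokens.txt").write_text(" ".join(tokens) + "\n")
    labels = [t for t in tokens if t != "$"]
    pd.DataFrame({"time_s": np.asarray(times, dtype=float),
                  "label": labels[:len(times)]}).to_csv(
        stem.with_name(stem.name + ".truth_times.csv"), index=False)


def load_truth(stem):
    stem = Path(stem)
    tokens = stem.with_name(stem.name + ".truth_tokens.txt").read_text().split()
    df = pd.read_csv(stem.with_name(stem.name + ".truth_times.csv"))
    return tokens, df["time_s"].to_numpy(dtype=float)
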