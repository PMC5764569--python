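"""Readers and writers for the pipeline's artifact formats.

Trial and lick tables travel as CSV (times in seconds, 6 decimal places);
trace bundles as an HDF5 container with /F_cell, /F_ring and a /meta table;
movies as multi-page TIFF with the two channels interleaved plus a JSON
sidecar carrying masks and true shifts.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synthgen import MovieStack

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_licks_csv",
    "read_licks_csv",
    "write_traces_h5",
    "read_traces_h5",
    "write_movie_tiff",
    "read_movie_tiff",
]

_TIME_COLS = ("tone_onset_s", "tone_offset_s", "reward_time_s", "timestamp_s")


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    for c in out.columns:
        if c in _TIME_COLS:
            out[c] = out[c].round(6)
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["rewarded"] = df["rewarded"].astype(bool)
    return df


def write_licks_csv(licks: np.ndarray, path, session_id: str = "s0") -> None:
    pd.DataFrame(
        {"timestamp_s": np.round(np.asarray(licks, dtype=float), 6), "session_id": session_id}
    ).to_csv(path, index=False, float_format="%.6f")


def read_licks_csv(path) -> np.ndarray:
    return pd.read_csv(path)["timestamp_s"].to_numpy()


def write_traces_h5(
    path, f_cell: np.ndarray, f_ring: np.ndarray | None, frame_rate_hz: float,
    meta: pd.DataFrame | None = None,
) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("F_cell", data=np.asarray(f_cell, dtype=np.float64))
        if f_ring is not None:
            h5.create_dataset("F_ring", data=np.asarray(f_ring, dtype=np.float64))
        grp = h5.create_group("meta")
        grp.attrs["frame_rate_hz"] = float(frame_rate_hz)
        if meta is not None:
            grp.attrs["columns"] = json.dumps(list(meta.columns))
            grp.create_dataset(
                "table", data=meta.to_csv(index=False).encode("utf-8")
            )


def read_traces_h5(path) -> dict:
    import io as _io

    with h5py.File(path, "r") as h5:
        out = {
            "F_cell": h5["F_cell"][...],
            "F_ring": h5["F_ring"][...] if "F_ring" in h5 else None,
            "frame_rate_hz": float(h5["meta"].attrs["frame_rate_hz"]),
            "meta": None,
        }
        if "table" in h5["meta"]:
            out["meta"] = pd.read_csv(_io.BytesIO(h5["meta/table"][()]))
    return out


def write_movie_tiff(stack: MovieStack, tiff_path, sidecar_path) -> None:
    """Channel-interleaved multi-page TIFF plus a JSON mask/shift sidecar."""
    t, h, w, c = stack.frames.shape
    pages = stack.frames.transpose(0, 3, 1, 2).reshape(t * c, h, w)
    tifffile.imwrite(tiff_path, pages.astype(np.float32))
    sidecar = {
        "frame_rate_hz": stack.frame_rate_hz,
        "n_channels": c,
        "roi_masks": [np.argwhere(m).tolist() for m in stack.roi_masks],
        "striosome_neuropil_mask": np.argwhere(stack.striosome_neuropil_mask).tolist(),
        "true_shifts": stack.true_shifts.tolist(),
        "shape": [t, h, w, c],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar))


def read_movie_tiff(tiff_path, sidecar_path) -> MovieStack:
    sidecar = json.loads(Path(sidecar_path).read_text())
    t, h, w, c = sidecar["shape"]
    pages = tifffile.imread(tiff_path)
    frames = pages.reshape(t, c, h, w).transpose(0, 2, 3, 1)

    def to_mask(coords):
        m = np.zeros((h, w), dtype=bool)
        if coords:
            idx = np.asarray(coords)
            m[idx[:, 0], idx[:, 1]] = True
        return m

    return MovieStack(
        frames=np.asarray(frames, dtype=np.float32),
        frame_rate_hz=float(sidecar["frame_rate_hz"]),
        roi_masks=[to_mask(cs) for cs in sidecar["roi_masks"]],
        striosome_neuropil_mask=to_mask(sidecar["striosome_neuropil_mask"]),
        true_shifts=np.asarray(sidecar["true_shifts"], dtype=int),
    )
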