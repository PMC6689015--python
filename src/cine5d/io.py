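"""Serialization: k-space bundles, schedules, traces, binnings, volumes.

A :class:`~cine5d.phantom.KSpaceBundle` is stored as a directory holding a
binary complex array (``lines.npy``) plus plain-text CSV tables (line
index table, ECG trigger list, bellows trace) and a JSON header.  Volumes
go to NIfTI with voxel spacing (mm) in the header; traces, schedules and
binnings go to CSV; reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .binning import RespBinning
from .motion import MotionTrace
from .phantom import KSpaceBundle
from .sampling import SamplingSchedule

__all__ = [
    "save_bundle", "load_bundle", "save_schedule", "load_schedule",
    "save_trace", "load_trace", "save_binning", "save_volume", "load_volume",
]


def save_bundle(bundle: KSpaceBundle, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "lines.npy", bundle.data)
    pd.DataFrame({
        "index": np.arange(bundle.n_lines),
        "ky": bundle.ky_idx, "kz": bundle.kz_idx, "t_ms": bundle.t_ms,
    }).to_csv(d / "lines.csv", index=False)
    pd.DataFrame({"t_ms": bundle.ecg_triggers_ms}).to_csv(
        d / "ecg_triggers.csv", index=False)
    pd.DataFrame({"t_ms": bundle.bellows_t_ms, "value": bundle.bellows}
                 ).to_csv(d / "bellows.csv", index=False)
    header = {
        "matrix_size": list(bundle.matrix_size),
        "fov_mm": list(bundle.fov_mm),
        "tr_ms": bundle.tr_ms,
        "partial_fourier": bundle.partial_fourier,
        "kspace_indexing": "DC at floor(N/2), 0-based",
    }
    (d / "header.json").write_text(json.dumps(header, indent=2))
    return d


def load_bundle(directory) -> KSpaceBundle:
    d = Path(directory)
    header = json.loads((d / "header.json").read_text())
    lines = pd.read_csv(d / "lines.csv")
    trig = pd.read_csv(d / "ecg_triggers.csv")
    bell = pd.read_csv(d / "bellows.csv")
    return KSpaceBundle(
        ky_idx=lines["ky"].to_numpy(), kz_idx=lines["kz"].to_numpy(),
        t_ms=lines["t_ms"].to_numpy(), data=np.load(d / "lines.npy"),
        ecg_triggers_ms=trig["t_ms"].to_numpy(),
        bellows_t_ms=bell["t_ms"].to_numpy(), bellows=bell["value"].to_numpy(),
        matrix_size=tuple(header["matrix_size"]),
        fov_mm=tuple(header["fov_mm"]), tr_ms=header["tr_ms"],
        partial_fourier=header["partial_fourier"],
    )


def save_schedule(schedule: SamplingSchedule, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(schedule.entries,
                      columns=["ky", "kz", "interleave", "ring"])
    df.insert(0, "index", np.arange(len(df)))
    df.to_csv(path, index=False)
    meta = path.with_suffix(".json")
    meta.write_text(json.dumps({
        "grid": list(schedule.grid), "circus_c": schedule.circus_c,
        "partial_fourier": schedule.partial_fourier,
    }))
    return path


def load_schedule(path) -> SamplingSchedule:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    entries = [tuple(int(v) for v in row)
               for row in df[["ky", "kz", "interleave", "ring"]].to_numpy()]
    return SamplingSchedule(entries=entries, grid=tuple(meta["grid"]),
                            circus_c=meta["circus_c"],
                            partial_fourier=meta["partial_fourier"])


def save_trace(trace: MotionTrace, path, hr_bpm=None) -> Path:
    df = pd.DataFrame({
        "beat_id": trace.beat_ids,
        "dx_mm": trace.displacement_mm[:, 0],
        "dy_mm": trace.displacement_mm[:, 1],
        "dz_mm": trace.displacement_mm[:, 2],
    })
    if hr_bpm is not None:
        df["hr_bpm"] = hr_bpm
    df.to_csv(path, index=False)
    return Path(path)


def load_trace(path) -> MotionTrace:
    df = pd.read_csv(path)
    return MotionTrace(
        beat_ids=df["beat_id"].to_numpy(),
        displacement_mm=df[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(),
        reference_beat_id=int(df["beat_id"].iloc[0]),
    )


def save_binning(binning: RespBinning, path) -> Path:
    df = pd.DataFrame({
        "beat_id": np.arange(len(binning.labels)),
        "cluster": binning.labels,
        "phase": [binning.phase_names[int(c)] for c in binning.labels],
    })
    df.to_csv(path, index=False)
    return Path(path)


def save_volume(volume: np.ndarray, spacing_mm, path) -> Path:
    """3D or 4D array to NIfTI with mm voxel spacing in the header."""
    affine = np.diag(list(spacing_mm[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(tuple(spacing_mm[:3]) + (1.0,) * (volume.ndim - 3))
    nib.save(img, str(path))
    return Path(path)


def load_volume(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(img.header.get_zooms()[:3])
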