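"""File I/O: NIfTI-1 volumes, SPM-dialect motion text, BIDS events tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import Bold4D, DataError, MotionTrace, OutlierMask, TaskDesign

__all__ = [
    "save_bold", "load_bold",
    "save_motion_trace", "load_motion_trace",
    "save_events", "load_events",
    "save_outlier_mask", "load_outlier_mask",
    "save_sidecar",
]


def save_bold(bold: Bold4D, path: str | Path) -> None:
    """Write a Bold4D as NIfTI-1 with voxel size and TR in the header."""
    affine = np.diag(list(bold.voxel_size) + [1.0])
    img = nib.Nifti1Image(bold.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(bold.voxel_size) + (bold.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold(path: str | Path, mask: np.ndarray | None = None) -> Bold4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise DataError(f"{path}: expected a 4D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Bold4D(data=data, voxel_size=tuple(float(z) for z in zooms[:3]),
                  tr=tr, mask=mask)


def save_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    """Six-column whitespace text (rp_*.txt dialect): mm, mm, mm, rad, rad, rad."""
    np.savetxt(str(path), trace.params, fmt="%+.8e")


def load_motion_trace(path: str | Path, provenance: str = "file") -> MotionTrace:
    params = np.loadtxt(str(path))
    if params.ndim == 1:
        params = params[np.newaxis, :]
    return MotionTrace(params=params, provenance=provenance)


def save_events(design: TaskDesign, path: str | Path) -> None:
    """BIDS events dialect: onset, duration, trial_type TSV."""
    rows = [{"onset": onset, "duration": dur, "trial_type": cond}
            for cond, onset, dur in sorted(design.events, key=lambda e: e[1])]
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).to_csv(
        str(path), sep="\t", index=False
    )


def load_events(path: str | Path, run_length: int, tr: float) -> TaskDesign:
    df = pd.read_csv(str(path), sep="\t")
    events = [(str(r.trial_type), float(r.onset), float(r.duration))
              for r in df.itertuples()]
    conditions = list(dict.fromkeys(e[0] for e in events))
    return TaskDesign(conditions=conditions, events=events,
                      run_length=run_length, tr=tr)


def save_outlier_mask(mask: OutlierMask, path: str | Path) -> None:
    """Single-column 0/1 text, one row per volume."""
    np.savetxt(str(path), mask.flags.astype(int), fmt="%d")


def load_outlier_mask(path: str | Path, metric: str = "manual",
                      threshold: float = 0.0) -> OutlierMask:
    flags = np.loadtxt(str(path)).astype(bool)
    if flags.ndim == 0:
        flags = flags[np.newaxis]
    return OutlierMask(flags=flags, metric=metric, threshold=threshold)


def save_sidecar(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
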