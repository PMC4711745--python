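"""Readers and writers: multi-channel TIFF + JSON sidecar, CSV cell tables.

The image format is a plain (optionally 4-D/5-D) TIFF holding the raw
intensity array, accompanied by a JSON sidecar carrying the physical
metadata (voxel size in μm, channel roles, frame times in minutes).
Intensities are stored as 32-bit floats, so round trips are lossless for
float32 data.  Missing metadata is an error, never a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .model import CELL_COLUMNS, CellRecord, ValidationError, VoxelGrid, frame_to_records, records_to_frame


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_volume(grid: VoxelGrid, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a VoxelGrid as float32 TIFF plus JSON metadata sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path)
    tifffile.imwrite(path, grid.data.astype(np.float32), photometric="minisblack")
    meta = {
        "voxel_size_um": list(grid.voxel_size),
        "channels": list(grid.channels),
        "axes": "tczyx" if grid.is_timelapse else "czyx",
    }
    if grid.frame_times is not None:
        meta["frame_times_min"] = [float(t) for t in grid.frame_times]
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> VoxelGrid:
    """Read a TIFF volume; the sidecar must supply voxel size and roles."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("voxel_size_um", "channels"):
        if key not in meta:
            raise ValidationError(f"sidecar missing required key {key!r}")
    data = tifffile.imread(path)
    frame_times = meta.get("frame_times_min")
    return VoxelGrid(
        data=data,
        voxel_size=tuple(meta["voxel_size_um"]),
        channels=tuple(meta["channels"]),
        frame_times=np.asarray(frame_times, dtype=float) if frame_times is not None else None,
    )


_CELL_HEADER = (
    "# per-cell image cytometry table; units: centroid/dist μm, volume μm³, MFI a.u.\n"
)


def write_cell_table(records: Sequence[CellRecord] | pd.DataFrame, path: str | Path) -> Path:
    """Write one CSV row per cell in the stable column order."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(_CELL_HEADER)
        df.to_csv(fh, index=False, columns=list(CELL_COLUMNS))
    return path


def read_cell_table(path: str | Path, as_records: bool = False):
    df = pd.read_csv(path, comment="#")
    return frame_to_records(df) if as_records else df


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
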