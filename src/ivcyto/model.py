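"""Core in-memory containers shared by every analysis stage.

The central object is :class:`VoxelGrid`, a role-labelled multi-channel
image volume with physical voxel size, optionally time-resolved.  Axis
order is fixed as ``(t,) c, z, y, x`` with 0-based indices; all physical
quantities are micrometres (μm) and minutes.  A voxel's physical position
is its index times the voxel size (voxel-centre convention); intervals
are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised channel roles.
CHANNEL_ROLES = ("vehicle", "payload", "damage", "macrophage", "vascular")


class ValidationError(ValueError):
    """Raised when a container or parameter set violates its invariants."""


@dataclass
class VoxelGrid:
    """Multi-channel intensity volume with physical metadata.

    Parameters
    ----------
    data:
        Array of shape ``(c, z, y, x)`` for a snapshot or
        ``(t, c, z, y, x)`` for a time-lapse, arbitrary units.
    voxel_size:
        Physical voxel size ``(z, y, x)`` in μm.
    channels:
        Role label per channel axis entry; each role from
        :data:`CHANNEL_ROLES`, each used at most once.
    frame_times:
        Acquisition time of each frame in minutes (time-lapse only),
        strictly increasing.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: tuple[str, ...]
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.channels = tuple(self.channels)
        if self.data.ndim not in (4, 5):
            raise ValidationError(
                f"data must be (c,z,y,x) or (t,c,z,y,x), got ndim={self.data.ndim}"
            )
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValidationError(f"unknown channel role {role!r}")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("duplicate channel role")
        c_axis = 0 if self.data.ndim == 4 else 1
        if self.data.shape[c_axis] != len(self.channels):
            raise ValidationError(
                f"{self.data.shape[c_axis]} channels in data but {len(self.channels)} roles"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.data.ndim != 5:
                raise ValidationError("frame_times given for a non-time-resolved grid")
            if len(self.frame_times) != self.data.shape[0]:
                raise ValidationError("frame_times length must equal number of frames")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValidationError("frame_times must be strictly increasing")

    # -- convenience accessors -------------------------------------------

    @property
    def is_timelapse(self) -> bool:
        return self.data.ndim == 5

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.is_timelapse else 1

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel_index(self, role: str) -> int:
        try:
            return self.channels.index(role)
        except ValueError:
            raise KeyError(f"channel role {role!r} not present (have {self.channels})") from None

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z,y,x)`` or ``(t,z,y,x)`` array for one role."""
        idx = self.channel_index(role)
        return self.data[idx] if self.data.ndim == 4 else self.data[:, idx]

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(data, self.voxel_size, self.channels, self.frame_times)


@dataclass
class LabelVolume:
    """Integer labelling of a volume; 0 is background, labels are 1..N."""

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3-D (z,y,x) array")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValidationError("labels must be integer-typed")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


#: Column order of the per-cell table (one row per segmented nucleus).
CELL_COLUMNS = (
    "cell_id",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "nucleus_volume_um3",
    "puncta_count",
    "vehicle_mfi",
    "payload_mfi",
    "dist_to_macrophage_um",
    "damage_class",
)


@dataclass
class CellRecord:
    """One segmented nucleus with its per-cell measurements.

    ``vehicle_mfi`` / ``payload_mfi`` are mean fluorescence intensities
    within the configured measurement radius of the nucleus surface;
    ``dist_to_macrophage_um`` is the Euclidean distance from the nucleus
    centroid to the nearest macrophage voxel.
    """

    cell_id: int
    centroid: tuple[float, float, float]  # (z, y, x) μm
    nucleus_volume: float  # μm³
    puncta_count: int
    vehicle_mfi: float
    payload_mfi: float
    dist_to_macrophage: float
    damage_class: str = "low"

    def __post_init__(self) -> None:
        if self.puncta_count < 0:
            raise ValidationError("puncta_count must be >= 0")
        if self.nucleus_volume <= 0:
            raise ValidationError("nucleus_volume must be > 0")
        if self.dist_to_macrophage < 0:
            raise ValidationError("dist_to_macrophage must be >= 0")
        if self.damage_class not in ("low", "high"):
            raise ValidationError(f"damage_class must be 'low' or 'high', got {self.damage_class!r}")


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Convert CellRecords to a DataFrame with the stable column order."""
    rows = [
        (
            r.cell_id,
            r.centroid[0],
            r.centroid[1],
            r.centroid[2],
            r.nucleus_volume,
            r.puncta_count,
            r.vehicle_mfi,
            r.payload_mfi,
            r.dist_to_macrophage,
            r.damage_class,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CELL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(
            cell_id=int(row.cell_id),
            centroid=(float(row.centroid_z_um), float(row.centroid_y_um), float(row.centroid_x_um)),
            nucleus_volume=float(row.nucleus_volume_um3),
            puncta_count=int(row.puncta_count),
            vehicle_mfi=float(row.vehicle_mfi),
            payload_mfi=float(row.payload_mfi),
            dist_to_macrophage=float(row.dist_to_macrophage_um),
            damage_class=str(row.damage_class),
        )
        for row in df.itertuples(index=False)
    ]
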