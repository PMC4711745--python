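"""Synthetic tumour volumes and vascular time-lapses with ground truth.

The generator emulates the statistical structure of intravital imaging
of a nanoparticle drug (vehicle + payload) in tumour tissue:

* nuclei are spheres placed by rejection sampling with a minimum centre
  separation of 1.5x the mean diameter (watershed-separable by design);
* a small fraction of cells (default 4%) are macrophages whose bodies
  form bright "depot" spheres of ~7 μm diameter in the vehicle and
  macrophage-label channels;
* the payload channel is the depot contribution spread by an isotropic
  exponential kernel exp(-d/λ) with λ = 15 μm, plus a diffuse
  background, scaled so that the mean intensity within 15 μm of depots
  is ``depot_fold_amplitude`` (default 3) times the far-field (>30 μm)
  mean before noise;
* per-nucleus DNA-damage puncta counts are Poisson with mean
  ``intercept + slope * local_dose`` where the local dose is the clean
  payload level averaged over the nucleus, in units of the near-depot
  target level (fold amplitude x background);
* vascular time-lapses decay exponentially with configurable half-lives
  (defaults 55 min vehicle, 61 min payload) and deposit a ~10% payload
  burst into perivascular tissue at the first post-injection frame;
* imaging noise is Poisson shot noise (strength set by ``photon_scale``)
  followed by additive Gaussian read noise.

All randomness comes from one ``numpy`` Generator seeded by
``config.seed``; identical (config, seed) pairs are bit-identical.
Draw order: nucleus radii, centres, macrophage flags, per-cell vehicle
uptake, puncta counts, puncta positions, then per-channel shot and read
noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .model import ValidationError, VoxelGrid


class PlacementError(RuntimeError):
    """Raised when overlap-free nucleus placement fails after bounded retries."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic tissue / time-lapse generator.

    Lengths are μm, times are minutes unless a field name says hours
    (``release_half_life_h``, ``snapshot_time_h``); intensities are a.u.
    """

    volume_shape: tuple[int, int, int] = (64, 256, 256)  # voxels (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)  # μm
    n_cells: int = 200
    macrophage_fraction: float = 0.04
    nucleus_radius_mean: float = 4.0  # μm
    nucleus_radius_sd: float = 0.5  # μm, truncated at 2 μm
    depot_diameter: float = 7.0  # μm
    depot_kernel_length: float = 15.0  # μm
    depot_fold_amplitude: float = 3.0
    burst_fraction: float = 0.10
    vehicle_half_life: float = 55.0  # min
    payload_half_life: float = 61.0  # min
    release_half_life_h: float = 15.0  # h
    dequench_fold: float = 7.0
    damage_link_intercept: float = 0.5  # puncta
    damage_link_slope: float = 4.0  # puncta per unit dose
    snapshot_time_h: float = 24.0  # h post injection for tissue snapshots
    # rendering amplitudes (a.u.)
    vehicle_background: float = 10.0
    payload_background: float = 10.0
    vehicle_depot_amplitude: float = 200.0
    vehicle_cell_uptake_median: float = 50.0  # a.u., per-cell lognormal
    vehicle_cell_uptake_sigma: float = 0.8  # log-space SD
    macrophage_label_amplitude: float = 100.0
    nuclear_fill: float = 50.0
    puncta_amplitude: float = 150.0
    puncta_sigma: float = 0.6  # μm
    vessel_intensity: float = 100.0  # t=0 intravascular signal
    tissue_autofluorescence: float = 2.0
    vessel_radius: float = 4.0  # μm
    burst_range: float = 10.0  # μm, perivascular shell thickness
    # noise
    photon_scale: float = 10.0  # photons per intensity unit; inf = no shot noise
    read_noise_sd: float = 1.0  # a.u.
    # time-lapse
    frame_interval: float = 5.0  # min
    n_frames: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.volume_shape) != 3 or any(v <= 0 for v in self.volume_shape):
            raise ValidationError(f"volume_shape must be 3 positive ints, got {self.volume_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size entries must be > 0")
        if not 0.0 <= self.macrophage_fraction <= 1.0:
            raise ValidationError("macrophage_fraction must be in [0, 1]")
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValidationError("burst_fraction must be in [0, 1]")
        for name in ("vehicle_half_life", "payload_half_life", "release_half_life_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.depot_fold_amplitude < 0:
            raise ValidationError("depot_fold_amplitude must be >= 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.depot_kernel_length <= 0:
            raise ValidationError("lengths must be > 0")
        if self.photon_scale <= 0:
            raise ValidationError("photon_scale must be > 0 (use inf to disable shot noise)")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")

    # -- presets ---------------------------------------------------------

    @classmethod
    def tissue_default(cls, **overrides) -> "SynthConfig":
        """Default snapshot-mode configuration (200 cells, 64x128x128 μm)."""
        return cls(**overrides)

    @classmethod
    def timelapse_default(cls, **overrides) -> "SynthConfig":
        """Default time-lapse configuration: a small vessel-containing
        field imaged every 5 min for 2 h."""
        overrides.setdefault("volume_shape", (16, 96, 96))
        overrides.setdefault("voxel_size", (2.0, 1.0, 1.0))
        return cls(**overrides)

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        d["voxel_size"] = list(self.voxel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown SynthConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class GroundTruth:
    """Per-cell ground truth of a generated volume.

    ``true_local_dose`` is the clean (noise-free, pre-de-quench) payload
    level averaged over the nucleus sphere, in units of the near-depot
    target level (``depot_fold_amplitude x payload_background``), so a
    depot-adjacent cell sits near dose 1 and far-field cells well below.
    ``n_macrophages`` records the Bernoulli draw
    exactly.  For time-lapses the per-cell arrays are empty and
    ``vessel_labels`` holds the vessel geometry.
    """

    cell_centroids: np.ndarray  # (n, 3) μm, z/y/x
    cell_radii: np.ndarray  # (n,) μm
    is_macrophage: np.ndarray  # (n,) bool
    true_puncta_counts: np.ndarray  # (n,) int
    true_local_dose: np.ndarray  # (n,) a.u.
    true_half_lives: dict = field(default_factory=dict)  # channel -> min
    vessel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.cell_centroids)
        for name in ("cell_radii", "is_macrophage", "true_puncta_counts", "true_local_dose"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length mismatch: expected {n}")
        self.true_puncta_counts = np.asarray(self.true_puncta_counts, dtype=int)
        if self.true_puncta_counts.size and self.true_puncta_counts.min() < 0:
            raise ValidationError("puncta counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_centroids)

    @property
    def n_macrophages(self) -> int:
        return int(np.count_nonzero(self.is_macrophage))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, self.n_cells + 1),
                "centroid_z_um": self.cell_centroids[:, 0] if self.n_cells else [],
                "centroid_y_um": self.cell_centroids[:, 1] if self.n_cells else [],
                "centroid_x_um": self.cell_centroids[:, 2] if self.n_cells else [],
                "radius_um": self.cell_radii,
                "is_macrophage": np.asarray(self.is_macrophage, dtype=bool),
                "true_puncta_count": self.true_puncta_counts,
                "true_local_dose": self.true_local_dose,
            }
        )

    def write(self, cells_csv: str | Path, scalars_json: str | Path) -> None:
        self.to_frame().to_csv(cells_csv, index=False)
        Path(scalars_json).write_text(
            json.dumps(
                {
                    "n_cells": self.n_cells,
                    "n_macrophages": self.n_macrophages,
                    "true_half_lives_min": self.true_half_lives,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _coord_axes(shape, voxel_size):
    return [np.arange(n) * v for n, v in zip(shape, voxel_size)]


def _sphere_box(shape, centre_um, radius_um, voxel_size):
    """Bounding-box slice and in-sphere mask for a sphere in a volume."""
    lo, hi = [], []
    for ax in range(3):
        lo.append(max(0, int(np.floor((centre_um[ax] - radius_um) / voxel_size[ax]))))
        hi.append(min(shape[ax], int(np.ceil((centre_um[ax] + radius_um) / voxel_size[ax])) + 1))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    if any(l >= h for l, h in zip(lo, hi)):
        return None, sl
    axes = [np.arange(l, h) * v - c for (l, h), v, c in zip(zip(lo, hi), voxel_size, centre_um)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return d2 <= radius_um**2, sl


def _paint_sphere(volume: np.ndarray, centre_um, radius_um, voxel_size, value=None, add=None):
    """Set (or add to) voxels whose centres lie within a sphere."""
    inside, sl = _sphere_box(volume.shape, centre_um, radius_um, voxel_size)
    if inside is None:
        return None, sl
    if value is not None:
        volume[sl][inside] = value
    if add is not None:
        volume[sl][inside] += add
    return inside, sl


def _place_centres(config: SynthConfig, radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centres with bounded retries.

    Minimum pairwise separation is 1.5x the mean nucleus diameter; every
    nucleus fits inside the volume with a half-voxel margin.
    """
    extent = np.array(
        [n * v for n, v in zip(config.volume_shape, config.voxel_size)]
    )
    min_sep = 1.5 * 2.0 * config.nucleus_radius_mean
    centres: list[np.ndarray] = []
    max_tries = max(2000, 1000 * config.n_cells)
    tries = 0
    for i in range(config.n_cells):
        margin = radii[i] + np.max(config.voxel_size)
        if np.any(extent - 2 * margin <= 0):
            raise PlacementError(
                f"volume extent {extent} too small for nucleus radius {radii[i]:.1f} μm"
            )
        while True:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"placed {len(centres)}/{config.n_cells} nuclei after {max_tries} tries; "
                    "volume too crowded for the requested separation"
                )
            cand = margin + rng.random(3) * (extent - 2 * margin)
            if not centres:
                break
            d = np.linalg.norm(np.array(centres) - cand, axis=1)
            if d.min() >= min_sep:
                break
        centres.append(cand)
    return np.array(centres).reshape(config.n_cells, 3)


def apply_imaging_noise(clean: np.ndarray, rng: np.random.Generator, photon_scale: float, read_noise_sd: float) -> np.ndarray:
    """Poisson shot noise then Gaussian read noise; clipped at zero.

    ``I -> Poisson(photon_scale * I) / photon_scale + N(0, read_noise_sd)``.
    An infinite ``photon_scale`` disables shot noise.
    """
    if np.isinf(photon_scale):
        noisy = clean.astype(float).copy()
    else:
        noisy = rng.poisson(np.clip(clean, 0, None) * photon_scale).astype(float) / photon_scale
    if read_noise_sd > 0:
        noisy += rng.normal(0.0, read_noise_sd, size=noisy.shape)
    return np.clip(noisy, 0.0, None)


def _depot_distance(depot_mask: np.ndarray, voxel_size) -> np.ndarray:
    """Euclidean distance (μm) from the depot mask; inf if no depots."""
    if not depot_mask.any():
        return np.full(depot_mask.shape, np.inf)
    return ndimage.distance_transform_edt(~depot_mask, sampling=voxel_size)


def dequench_multiplier(config: SynthConfig) -> float:
    """Payload fluorescence gain at the snapshot time.

    The pro-drug reporter is quenched inside the intact particle and
    brightens up to ``dequench_fold`` as the payload is reduced; the ramp
    is first order with the release half-life.
    """
    released = 1.0 - 2.0 ** (-config.snapshot_time_h / config.release_half_life_h)
    return 1.0 + (config.dequench_fold - 1.0) * released


# ---------------------------------------------------------------------------
# snapshot-mode generator


def generate_tissue(config: SynthConfig) -> tuple[VoxelGrid, GroundTruth]:
    """Generate a 4-channel tumour snapshot and its ground truth.

    Channels: ``vehicle`` (bright macrophage depots over a diffuse
    background), ``payload`` (depot signal spread by the exponential
    kernel, de-quenched at the snapshot time), ``damage`` (nuclear fill
    plus dose-linked puncta) and ``macrophage`` (depot label).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.volume_shape
    vs = config.voxel_size

    # 1) nucleus radii (truncated normal, >= 2 μm)
    radii = np.empty(config.n_cells)
    for i in range(config.n_cells):
        r = rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd)
        while r < 2.0:
            r = rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd)
        radii[i] = r

    # 2) centres, 3) macrophage flags, 4) per-cell vehicle uptake
    centres = _place_centres(config, radii, rng)
    is_mac = rng.random(config.n_cells) < config.macrophage_fraction
    uptake = (
        rng.lognormal(np.log(max(config.vehicle_cell_uptake_median, 1e-12)),
                      config.vehicle_cell_uptake_sigma, size=config.n_cells)
        if config.vehicle_cell_uptake_median > 0
        else np.zeros(config.n_cells)
    )

    # depot + nucleus masks
    depot_mask = np.zeros(shape, dtype=bool)
    depot_r = config.depot_diameter / 2.0
    for i in np.flatnonzero(is_mac):
        _paint_sphere(depot_mask, centres[i], depot_r, vs, value=True)

    nuclear = np.zeros(shape, dtype=float)
    for i in range(config.n_cells):
        _paint_sphere(nuclear, centres[i], radii[i], vs, value=config.nuclear_fill)

    # payload field: bg + c * exp(-d/λ), scaled to the near/far fold target
    d = _depot_distance(depot_mask, vs)
    bg = config.payload_background
    kernel = np.where(np.isinf(d), 0.0, np.exp(-np.minimum(d, 700 * config.depot_kernel_length) / config.depot_kernel_length))
    # calibration bins match the proximity-profile convention:
    # near = (0, L) exclusive of depot voxels, far = [2L, inf)
    near = (d > 0) & (d < config.depot_kernel_length)
    far = d >= 2.0 * config.depot_kernel_length
    if depot_mask.any() and near.any() and far.any():
        m_near = float(kernel[near].mean())
        m_far = float(kernel[far].mean())
        denom = m_near - config.depot_fold_amplitude * m_far
        if denom <= 0:
            raise ValidationError(
                "depot_fold_amplitude unreachable: far-field kernel mass too large "
                "(volume too small for the kernel length)"
            )
        c = bg * (config.depot_fold_amplitude - 1.0) / denom
    else:
        c = 0.0
    payload_clean = bg + c * kernel

    # per-cell dose: clean payload averaged over the nucleus sphere, in
    # units of the near-depot target level (fold_amplitude x background),
    # so a depot-adjacent cell sits near dose 1 and far-field cells well
    # below it; this keeps Poisson puncta counts in the countable range
    dose_unit = max(config.depot_fold_amplitude, 1.0) * bg
    dose = np.empty(config.n_cells)
    for i in range(config.n_cells):
        box, sl = _sphere_box(shape, centres[i], radii[i], vs)
        if box is None or not box.any():
            at = tuple(int(round(centres[i][ax] / vs[ax])) for ax in range(3))
            dose[i] = payload_clean[at] / dose_unit
        else:
            dose[i] = payload_clean[sl][box].mean() / dose_unit
    lam_puncta = config.damage_link_intercept + config.damage_link_slope * dose
    counts = rng.poisson(np.clip(lam_puncta, 0, None)) if config.n_cells else np.zeros(0, dtype=int)

    # damage channel: nuclear fill + Gaussian puncta
    damage = nuclear.copy()
    sigma = config.puncta_sigma
    for i in range(config.n_cells):
        placed: list[np.ndarray] = []
        inner = 0.75 * radii[i]
        for _ in range(int(counts[i])):
            pos = None
            for _try in range(60):
                u = rng.normal(size=3)
                u /= max(np.linalg.norm(u), 1e-12)
                rad = inner * rng.random() ** (1 / 3)
                cand = centres[i] + u * rad
                if not placed or np.min(np.linalg.norm(np.array(placed) - cand, axis=1)) >= 3.0 * sigma:
                    pos = cand
                    break
            if pos is None:
                pos = cand  # accept a crowded spot rather than dropping it
            placed.append(pos)
            _add_gaussian_spot(damage, pos, sigma, config.puncta_amplitude, vs)

    # vehicle: diffuse background + heterogeneous per-cell uptake bodies
    # (cell-sized blobs; macrophages carry the bright depot amplitude)
    vehicle_clean = np.full(shape, config.vehicle_background)
    for i in range(config.n_cells):
        if not is_mac[i]:
            _paint_sphere(vehicle_clean, centres[i], 1.1 * radii[i], vs, add=uptake[i])
    vehicle_clean = vehicle_clean + config.vehicle_depot_amplitude * depot_mask
    mac_clean = config.macrophage_label_amplitude * depot_mask
    payload_out = payload_clean * dequench_multiplier(config)

    clean = np.stack([vehicle_clean, payload_out, damage, mac_clean])
    noisy = np.stack(
        [apply_imaging_noise(clean[k], rng, config.photon_scale, config.read_noise_sd) for k in range(4)]
    )

    grid = VoxelGrid(noisy, vs, ("vehicle", "payload", "damage", "macrophage"))
    gt = GroundTruth(
        cell_centroids=centres,
        cell_radii=radii,
        is_macrophage=is_mac,
        true_puncta_counts=counts,
        true_local_dose=dose,
        true_half_lives={},
    )
    return grid, gt


def _add_gaussian_spot(volume: np.ndarray, centre_um, sigma_um: float, amplitude: float, voxel_size) -> None:
    reach = 3.0 * sigma_um
    shape = volume.shape
    lo = [max(0, int(np.floor((centre_um[ax] - reach) / voxel_size[ax]))) for ax in range(3)]
    hi = [min(shape[ax], int(np.ceil((centre_um[ax] + reach) / voxel_size[ax])) + 1) for ax in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    axes = [np.arange(l, h) * v - c for (l, h), v, c in zip(zip(lo, hi), voxel_size, centre_um)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    volume[sl] += amplitude * np.exp(-d2 / (2.0 * sigma_um**2))


# ---------------------------------------------------------------------------
# time-lapse generator


def _vessel_geometry(config: SynthConfig) -> np.ndarray:
    """Two straight vessels (cylinders along x) as a label volume."""
    shape = config.volume_shape
    vs = config.voxel_size
    z, y = np.meshgrid(
        np.arange(shape[0]) * vs[0], np.arange(shape[1]) * vs[1], indexing="ij"
    )
    extent_z = shape[0] * vs[0]
    extent_y = shape[1] * vs[1]
    labels2d = np.zeros(shape[:2], dtype=np.int32)
    for lab, (fz, fy) in enumerate([(0.35, 0.3), (0.65, 0.7)], start=1):
        inside = (z - fz * extent_z) ** 2 + (y - fy * extent_y) ** 2 <= config.vessel_radius**2
        labels2d[inside] = lab
    return np.repeat(labels2d[:, :, None], shape[2], axis=2)


def generate_timelapse(config: SynthConfig) -> tuple[VoxelGrid, GroundTruth]:
    """Generate a 3-channel vascular time-lapse and its ground truth.

    Frame 0 is a pre-injection background frame (the background-
    subtraction reference); from frame 1 onward the intravascular
    vehicle and payload signals decay as ``I0 * exp(-ln2 (t - t1)/t_half)``
    with the configured half-lives, and a ``burst_fraction`` share of the
    payload's initial intravascular integral sits in a perivascular
    shell.  The ``vascular`` channel is a constant tracer marking the
    vessels in every frame.
    """
    if config.n_frames < 4:
        raise ValidationError("n_frames must be >= 4")
    if config.frame_interval <= 0:
        raise ValidationError("frame_interval must be > 0")
    rng = np.random.default_rng(config.seed)
    shape = config.volume_shape
    vs = config.voxel_size

    vessels = _vessel_geometry(config)
    vessel_mask = vessels > 0
    shell_dist = ndimage.distance_transform_edt(~vessel_mask, sampling=vs)
    shell = (shell_dist > 0) & (shell_dist <= config.burst_range)

    bg = config.tissue_autofluorescence
    i0 = config.vessel_intensity
    n_vessel = int(vessel_mask.sum())
    n_shell = int(shell.sum())
    burst_level = (
        config.burst_fraction * i0 * n_vessel / n_shell if n_shell else 0.0
    )

    times = np.arange(config.n_frames) * config.frame_interval
    t1 = times[1]
    frames = []
    for f, t in enumerate(times):
        vehicle = np.full(shape, bg)
        payload = np.full(shape, bg)
        vascular = np.full(shape, bg)
        vascular[vessel_mask] += config.macrophage_label_amplitude
        if f >= 1:
            dec_v = np.exp(-np.log(2.0) * (t - t1) / config.vehicle_half_life)
            dec_p = np.exp(-np.log(2.0) * (t - t1) / config.payload_half_life)
            vehicle[vessel_mask] += i0 * dec_v
            payload[vessel_mask] += i0 * dec_p
            payload[shell] += burst_level
        frames.append(np.stack([vehicle, payload, vascular]))
    clean = np.stack(frames)  # (t, c, z, y, x)

    noisy = np.empty_like(clean)
    for c in range(clean.shape[1]):
        noisy[:, c] = apply_imaging_noise(clean[:, c], rng, config.photon_scale, config.read_noise_sd)

    grid = VoxelGrid(
        noisy,
        vs,
        ("vehicle", "payload", "vascular"),
        frame_times=times,
    )
    gt = GroundTruth(
        cell_centroids=np.zeros((0, 3)),
        cell_radii=np.zeros(0),
        is_macrophage=np.zeros(0, dtype=bool),
        true_puncta_counts=np.zeros(0, dtype=int),
        true_local_dose=np.zeros(0),
        true_half_lives={
            "vehicle": config.vehicle_half_life,
            "payload": config.payload_half_life,
        },
        vessel_labels=vessels,
    )
    return grid, gt
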