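"""Single-cell 3-D image cytometry.

Nuclei are segmented from the nuclear damage-reporter channel
(smooth -> threshold -> fill -> distance transform -> peak-seeded
watershed -> volume filter), DNA-damage puncta are counted per nucleus
by Laplacian-of-Gaussian blob detection, and the local drug level of
each cell is the mean fluorescence intensity (MFI) within a physical
radius of the nucleus surface.  Cells are classed high/low damage by a
puncta-count threshold and the damage-dose association is quantified as
a high/low MFI ratio plus a one-way ANOVA across damage bins, after the
2-standard-deviation outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import blob_log
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .model import LabelVolume, ValidationError, VoxelGrid

DEFAULT_DAMAGE_THRESHOLD = 5  # puncta; "many puncta" cut-off, configurable
DEFAULT_MFI_RADIUS = 5.0  # μm from the nucleus surface


@dataclass
class SegmentationParams:
    """Nuclear segmentation parameters (lengths μm, volumes μm³)."""

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.0
    min_volume: float = 50.0
    max_volume: float = 1500.0
    watershed_min_distance: float = 9.0

    def __post_init__(self) -> None:
        if self.min_volume >= self.max_volume:
            raise ValidationError("min_volume must be < max_volume")
        if self.smoothing_sigma <= 0 or self.watershed_min_distance <= 0:
            raise ValidationError("lengths must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class PunctaParams:
    """Puncta (spot) detection parameters.

    ``detection_threshold`` is relative: a spot must rise above the
    nucleus median by at least this fraction of the median, which makes
    counts invariant to uniform intensity scaling.
    """

    spot_sigma_range: tuple[float, float] = (0.4, 1.0)  # μm
    detection_threshold: float = 0.5
    min_separation: float = 1.2  # μm

    def __post_init__(self) -> None:
        self.spot_sigma_range = tuple(float(v) for v in self.spot_sigma_range)
        lo, hi = self.spot_sigma_range
        if not 0 < lo <= hi:
            raise ValidationError("spot_sigma_range must be 0 < lo <= hi")
        if self.detection_threshold <= 0:
            raise ValidationError("detection_threshold must be > 0")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be >= 0")


def _distance_peaks(edt: np.ndarray, min_distance_um: float, voxel_size) -> np.ndarray:
    """Deterministic watershed seeds from a distance transform.

    Candidate peaks are regional maxima under a separable box maximum
    filter whose half-width is ``min_distance_um / sqrt(3)`` per axis
    (the largest box guaranteed not to suppress peaks that are
    ``min_distance_um`` apart in Euclidean terms); candidates are then
    greedily suppressed to the exact Euclidean minimum distance, ties
    broken by peak height then lowest linear index.  Returns ``(k, 3)``
    voxel coordinates.
    """
    size = [2 * max(1, int(round(min_distance_um / np.sqrt(3.0) / v))) + 1 for v in voxel_size]
    local_max = (edt == ndimage.maximum_filter(edt, size=size)) & (edt > 0)
    coords = np.argwhere(local_max)
    if coords.size == 0:
        return coords.reshape(0, 3)
    heights = edt[tuple(coords.T)]
    linear = np.ravel_multi_index(tuple(coords.T), edt.shape)
    order = np.lexsort((linear, -heights))
    coords = coords[order]
    vs = np.asarray(voxel_size)
    accepted: list[np.ndarray] = []
    for p in coords:
        pos = p * vs
        if accepted and np.min(
            np.linalg.norm(np.array(accepted) - pos, axis=1)
        ) < min_distance_um:
            continue
        accepted.append(pos)
    return np.array([np.round(a / vs).astype(int) for a in accepted])


def segment_nuclei(grid: VoxelGrid, params: SegmentationParams | None = None) -> LabelVolume:
    """Segment nuclei from the damage-reporter channel.

    Pipeline: Gaussian smoothing (physical sigma), global threshold
    (Otsu or fixed), hole filling, Euclidean distance transform,
    peak-seeded watershed with peaks at least ``watershed_min_distance``
    apart, then a [min_volume, max_volume] filter; labels are relabelled
    contiguously.  An empty image yields zero labels, not an error.
    """
    params = params or SegmentationParams()
    img = grid.channel("damage").astype(float)
    if img.ndim != 3:
        raise ValidationError("segmentation expects a snapshot (z,y,x) grid")
    vs = grid.voxel_size
    sigma_vox = [params.smoothing_sigma / v for v in vs]
    smoothed = gaussian(img, sigma=sigma_vox, preserve_range=True)

    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return LabelVolume(np.zeros(img.shape, dtype=np.int32), provenance="segment_nuclei")
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    binary = smoothed > thr
    if not binary.any():
        return LabelVolume(np.zeros(img.shape, dtype=np.int32), provenance="segment_nuclei")
    binary = ndimage.binary_fill_holes(binary)

    edt = ndimage.distance_transform_edt(binary, sampling=vs)
    peaks = _distance_peaks(edt, params.watershed_min_distance, vs)
    markers = np.zeros(img.shape, dtype=np.int32)
    for k, p in enumerate(peaks, start=1):
        markers[tuple(p)] = k
    labels = watershed(-edt, markers=markers, mask=binary)

    voxel_vol = float(np.prod(vs))
    out = np.zeros(img.shape, dtype=np.int32)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        vol = m.sum() * voxel_vol
        if params.min_volume <= vol <= params.max_volume:
            out[m] = next_id
            next_id += 1
    return LabelVolume(out, provenance="segment_nuclei")


def detect_puncta(grid: VoxelGrid, nuclei: LabelVolume, params: PunctaParams | None = None) -> np.ndarray:
    """Count DNA-damage puncta inside each nucleus.

    Multiscale LoG blob detection runs on each nucleus' bounding box of
    the damage channel, normalised by the nucleus median; blobs outside
    the nucleus mask or below ``detection_threshold`` (relative to the
    median) are discarded, and blobs closer than ``min_separation`` are
    merged keeping the strongest.  Returns counts indexed by label-1.
    """
    params = params or PunctaParams()
    img = grid.channel("damage").astype(float)
    vs = np.asarray(grid.voxel_size)
    labels = nuclei.labels
    n = nuclei.n_labels
    counts = np.zeros(n, dtype=int)
    if n == 0:
        return counts
    lo_sig, hi_sig = params.spot_sigma_range
    min_sigma = np.maximum(lo_sig / vs, 0.5)
    max_sigma = np.maximum(hi_sig / vs, min_sigma)
    objects = ndimage.find_objects(labels)
    pad = [int(np.ceil(3 * hi_sig / v)) for v in vs]
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        psl = tuple(
            slice(max(0, s.start - p), min(dim, s.stop + p))
            for s, p, dim in zip(sl, pad, img.shape)
        )
        sub = img[psl]
        submask = labels[psl] == lab
        med = float(np.median(sub[submask]))
        scale = max(med, 1e-12)
        rel = (sub - med) / scale
        blobs = blob_log(
            rel,
            min_sigma=min_sigma,
            max_sigma=max_sigma,
            num_sigma=3,
            threshold=0.05 * params.detection_threshold,
        )
        kept = []
        for b in blobs:
            idx = tuple(int(round(c)) for c in b[:3])
            if not submask[idx]:
                continue
            if rel[idx] < params.detection_threshold:
                continue
            pos_um = np.array(idx) * vs
            kept.append((rel[idx], pos_um))
        # merge blobs closer than min_separation, keeping the strongest
        kept.sort(key=lambda t: -t[0])
        accepted: list[np.ndarray] = []
        for strength, pos in kept:
            if accepted and np.min(
                np.linalg.norm(np.array(accepted) - pos, axis=1)
            ) < params.min_separation:
                continue
            accepted.append(pos)
        counts[lab - 1] = len(accepted)
    return counts


def measure_local_mfi(grid: VoxelGrid, nuclei: LabelVolume, radius: float, channel: str) -> np.ndarray:
    """Per-cell MFI within ``radius`` μm of the nucleus surface.

    The measurement region is the nucleus mask dilated by the physical
    radius (anisotropy-aware Euclidean distance), nucleus voxels
    included; ``radius=0`` measures over the nucleus mask only.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    img = grid.channel(channel).astype(float)
    if img.ndim != 3:
        raise ValidationError("measure_local_mfi expects a snapshot grid")
    vs = grid.voxel_size
    labels = nuclei.labels
    n = nuclei.n_labels
    out = np.full(n, np.nan)
    objects = ndimage.find_objects(labels)
    pad = [int(np.ceil(radius / v)) + 1 for v in vs]
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        psl = tuple(
            slice(max(0, s.start - p), min(dim, s.stop + p))
            for s, p, dim in zip(sl, pad, img.shape)
        )
        m = labels[psl] == lab
        if radius == 0:
            region = m
        else:
            dist = ndimage.distance_transform_edt(~m, sampling=vs)
            region = dist <= radius
        out[lab - 1] = img[psl][region].mean()
    return out


def classify_damage(puncta_counts, threshold: int = DEFAULT_DAMAGE_THRESHOLD):
    """High/low damage classes and the high-damage fraction."""
    if threshold < 1:
        raise ValidationError("damage threshold must be >= 1")
    counts = np.asarray(puncta_counts, dtype=int)
    classes = np.where(counts >= threshold, "high", "low")
    frac = float((counts >= threshold).mean()) if counts.size else 0.0
    return classes, frac


def exclude_outliers(values) -> np.ndarray:
    """Single-pass 2-SD outlier rule.

    Retains values with ``|x - mean| <= 2 SD`` where mean and sample SD
    (n-1 denominator) come from the full input; zero variance retains
    everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 values for outlier exclusion")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= 2.0 * sd


#: Default puncta-count bin edges for the damage-level ANOVA.
DEFAULT_DAMAGE_BINS = (0, 2, 5, 10)


def dose_damage_association(
    cells: pd.DataFrame,
    damage_threshold: int = DEFAULT_DAMAGE_THRESHOLD,
    damage_bins: tuple = DEFAULT_DAMAGE_BINS,
) -> dict:
    """Association between local drug level and DNA-damage response.

    For each channel (payload, vehicle): apply the 2-SD outlier rule to
    the MFIs, report mean MFI in high- vs low-damage cells and their
    ratio, and a one-way ANOVA of MFI across puncta-count bins.
    """
    required = {"puncta_count", "payload_mfi", "vehicle_mfi"}
    missing = required - set(cells.columns)
    if missing:
        raise ValidationError(f"cell table missing columns: {sorted(missing)}")
    counts = cells["puncta_count"].to_numpy(dtype=int)
    result: dict = {"damage_threshold": damage_threshold, "damage_bins": list(damage_bins)}
    edges = list(damage_bins) + [np.inf]
    for channel in ("payload", "vehicle"):
        mfi = cells[f"{channel}_mfi"].to_numpy(dtype=float)
        keep = exclude_outliers(mfi)
        m, c = mfi[keep], counts[keep]
        high = m[c >= damage_threshold]
        low = m[c < damage_threshold]
        entry: dict = {
            "n_cells": int(keep.sum()),
            "n_excluded": int((~keep).sum()),
            "n_high": int(high.size),
            "n_low": int(low.size),
        }
        if high.size and low.size:
            entry["mean_high"] = float(high.mean())
            entry["mean_low"] = float(low.mean())
            entry["ratio_high_low"] = (
                float(high.mean() / low.mean()) if low.mean() != 0 else float("nan")
            )
            entry["flag"] = None
        else:
            entry["mean_high"] = float(high.mean()) if high.size else float("nan")
            entry["mean_low"] = float(low.mean()) if low.size else float("nan")
            entry["ratio_high_low"] = float("nan")
            entry["flag"] = "empty damage class; ratio undefined"
        groups = [
            m[(c >= lo) & (c < hi)]
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) >= 2:
            fstat, p = stats.f_oneway(*groups)
            entry["anova_f"] = float(fstat)
            entry["anova_p"] = float(p)
        else:
            entry["anova_f"] = float("nan")
            entry["anova_p"] = float("nan")
            entry["flag"] = entry.get("flag") or "too few occupied damage bins for ANOVA"
        result[channel] = entry
    return result


# ---------------------------------------------------------------------------
# table assembly


def macrophage_mask(grid: VoxelGrid, threshold: float | None = None) -> np.ndarray:
    """Boolean macrophage mask from the macrophage-label channel."""
    img = grid.channel("macrophage")
    if threshold is None:
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        threshold = threshold_otsu(img)
    return img > threshold


def build_cell_table(
    grid: VoxelGrid,
    nuclei: LabelVolume | None = None,
    seg_params: SegmentationParams | None = None,
    puncta_params: PunctaParams | None = None,
    mfi_radius: float = DEFAULT_MFI_RADIUS,
    damage_threshold: int = DEFAULT_DAMAGE_THRESHOLD,
) -> pd.DataFrame:
    """Run the full per-cell pipeline and return the cell table."""
    if nuclei is None:
        nuclei = segment_nuclei(grid, seg_params)
    vs = grid.voxel_size
    counts = detect_puncta(grid, nuclei, puncta_params)
    vehicle = measure_local_mfi(grid, nuclei, mfi_radius, "vehicle")
    payload = measure_local_mfi(grid, nuclei, mfi_radius, "payload")
    classes, _ = classify_damage(counts, damage_threshold)

    mac = macrophage_mask(grid)
    if mac.any():
        dist_map = ndimage.distance_transform_edt(~mac, sampling=vs)
    else:
        dist_map = np.full(grid.spatial_shape, np.inf)

    n = nuclei.n_labels
    ids = list(range(1, n + 1))
    centroids = ndimage.center_of_mass(np.ones_like(nuclei.labels), nuclei.labels, ids) if n else []
    voxel_vol = float(np.prod(vs))
    volumes = ndimage.sum_labels(np.ones_like(nuclei.labels), nuclei.labels, ids) * voxel_vol if n else []
    rows = []
    for k, lab in enumerate(ids):
        cz, cy, cx = centroids[k]
        centroid_um = (cz * vs[0], cy * vs[1], cx * vs[2])
        d = float(dist_map[int(round(cz)), int(round(cy)), int(round(cx))])
        rows.append(
            (
                lab,
                *centroid_um,
                float(volumes[k]),
                int(counts[k]),
                float(vehicle[k]),
                float(payload[k]),
                d,
                classes[k],
            )
        )
    from .model import CELL_COLUMNS

    return pd.DataFrame(rows, columns=list(CELL_COLUMNS))
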