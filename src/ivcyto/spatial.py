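"""Spatial statistics: co-localization, heterogeneity and proximity.

Pearson correlation and Manders M1/M2 quantify vehicle/payload
co-localization over a mask; the coefficient of variation (CV) of MFIs
over a regular tiling of cell-sized ROIs quantifies spatial
heterogeneity; and the macrophage-proximity profile bins channel
intensity by Euclidean distance from the macrophage (depot) mask to
measure near-depot drug enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .model import ValidationError, VoxelGrid

DEFAULT_ROI_SIZE = 10.0  # μm, "cell-sized" tiling for the CV
DEFAULT_NEAR_CUT = 15.0  # μm, one cell-length from a macrophage


@dataclass
class ColocResult:
    pearson_rho: float = float("nan")
    manders_m1: float = float("nan")
    manders_m2: float = float("nan")
    threshold_a: float = float("nan")
    threshold_b: float = float("nan")
    n_voxels: int = 0
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "pearson_rho": self.pearson_rho,
            "manders_m1": self.manders_m1,
            "manders_m2": self.manders_m2,
            "threshold_a": self.threshold_a,
            "threshold_b": self.threshold_b,
            "n_voxels": self.n_voxels,
            "flag": self.flag,
        }


@dataclass
class HeterogeneityResult:
    cv: float
    roi_size: float  # μm
    n_rois: int
    mean_mfi: float = float("nan")
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "cv": self.cv,
            "roi_size_um": self.roi_size,
            "n_rois": self.n_rois,
            "mean_mfi": self.mean_mfi,
            "flag": self.flag,
        }


@dataclass
class ProximityProfile:
    bin_edges: np.ndarray  # μm
    mean_intensity: np.ndarray  # per bin, a.u.
    fold_vs_far: float
    near_cut: float = DEFAULT_NEAR_CUT
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "bin_edges_um": list(map(float, self.bin_edges)),
            "mean_intensity": list(map(float, self.mean_intensity)),
            "fold_vs_far": self.fold_vs_far,
            "near_cut_um": self.near_cut,
            "flag": self.flag,
        }


def _masked_pair(grid: VoxelGrid, channel_a: str, channel_b: str, mask):
    a = grid.channel(channel_a).astype(float)
    b = grid.channel(channel_b).astype(float)
    if a.ndim != 3:
        raise ValidationError("co-localization expects a snapshot grid")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValidationError("mask shape must match the spatial shape")
    return a, b, mask


def pearson_coloc(grid: VoxelGrid, channel_a: str, channel_b: str, mask=None) -> ColocResult:
    """Pearson correlation of two channels over masked voxels."""
    a, b, mask = _masked_pair(grid, channel_a, channel_b, mask)
    av, bv = a[mask], b[mask]
    if av.size < 2:
        raise ValidationError("mask must contain at least 2 voxels")
    if av.std() == 0 or bv.std() == 0:
        return ColocResult(n_voxels=av.size, flag="zero variance; Pearson undefined")
    rho = float(np.corrcoef(av, bv)[0, 1])
    return ColocResult(pearson_rho=rho, n_voxels=av.size)


def background_percentile_thresholds(
    grid: VoxelGrid, channel_a: str, channel_b: str, mask, percentile: float = 95.0
) -> tuple[float, float]:
    """Default Manders thresholds: a high percentile of each channel's
    out-of-mask background."""
    a, b, mask = _masked_pair(grid, channel_a, channel_b, mask)
    outside = ~mask
    if not outside.any():
        # the mask covers everything: fall back to the in-mask percentile
        outside = mask
    return (
        float(np.percentile(a[outside], percentile)),
        float(np.percentile(b[outside], percentile)),
    )


def manders_coloc(
    grid: VoxelGrid,
    channel_a: str,
    channel_b: str,
    mask=None,
    thresholds: tuple[float, float] | None = None,
) -> ColocResult:
    """Manders M1/M2 over masked voxels.

    M1 is the fraction of above-threshold channel-A intensity found at
    voxels where channel B is also above its threshold; M2 is the
    symmetric quantity.  Default thresholds are the 95th percentile of
    each channel outside the mask (background percentile rule).
    """
    a, b, mask = _masked_pair(grid, channel_a, channel_b, mask)
    if thresholds is None:
        thresholds = background_percentile_thresholds(grid, channel_a, channel_b, mask)
    ta, tb = map(float, thresholds)
    if ta < 0 or tb < 0:
        raise ValidationError("thresholds must be >= 0")
    av, bv = a[mask], b[mask]
    a_on, b_on = av > ta, bv > tb
    denom1 = float(av[a_on].sum())
    denom2 = float(bv[b_on].sum())
    res = ColocResult(threshold_a=ta, threshold_b=tb, n_voxels=av.size)
    if denom1 == 0 or denom2 == 0:
        res.flag = "no above-threshold signal; Manders undefined"
        return res
    res.manders_m1 = float(av[a_on & b_on].sum() / denom1)
    res.manders_m2 = float(bv[a_on & b_on].sum() / denom2)
    return res


def spatial_cv(
    grid: VoxelGrid,
    channel: str,
    roi_size: float = DEFAULT_ROI_SIZE,
    mask=None,
    min_coverage: float = 0.5,
) -> HeterogeneityResult:
    """Coefficient of variation of MFIs over a regular ROI tiling.

    The volume is tiled into non-overlapping boxes of ``roi_size`` μm
    per axis; ROIs with less than ``min_coverage`` of their voxels in
    the mask are discarded; CV = sample SD / mean of the per-ROI MFIs.
    """
    if roi_size <= 0:
        raise ValidationError("roi_size must be > 0")
    img = grid.channel(channel).astype(float)
    if img.ndim != 3:
        raise ValidationError("spatial_cv expects a snapshot grid")
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    steps = [max(1, int(round(roi_size / v))) for v in grid.voxel_size]
    mfis = []
    nz, ny, nx = img.shape
    for z0 in range(0, nz - steps[0] + 1, steps[0]):
        for y0 in range(0, ny - steps[1] + 1, steps[1]):
            for x0 in range(0, nx - steps[2] + 1, steps[2]):
                sl = (
                    slice(z0, z0 + steps[0]),
                    slice(y0, y0 + steps[1]),
                    slice(x0, x0 + steps[2]),
                )
                m = mask[sl]
                if m.mean() < min_coverage:
                    continue
                mfis.append(img[sl][m].mean())
    mfis = np.asarray(mfis)
    if mfis.size < 2:
        raise ValidationError("fewer than 2 complete ROIs inside the mask")
    mean = float(mfis.mean())
    if mean == 0:
        return HeterogeneityResult(
            cv=float("nan"), roi_size=roi_size, n_rois=mfis.size, mean_mfi=0.0,
            flag="zero mean MFI; CV undefined",
        )
    return HeterogeneityResult(
        cv=float(mfis.std(ddof=1) / mean),
        roi_size=roi_size,
        n_rois=int(mfis.size),
        mean_mfi=mean,
    )


def proximity_profile(
    grid: VoxelGrid,
    channel: str,
    macrophage_mask,
    bin_edges,
    near_cut: float = DEFAULT_NEAR_CUT,
) -> ProximityProfile:
    """Mean channel intensity binned by distance from the macrophage mask.

    The distance transform uses physical voxel spacing, macrophage
    voxels themselves are excluded, and ``fold_vs_far`` is the mean over
    [0, near_cut) divided by the mean beyond the last interior edge.
    """
    img = grid.channel(channel).astype(float)
    if img.ndim != 3:
        raise ValidationError("proximity_profile expects a snapshot grid")
    mac = np.asarray(macrophage_mask, dtype=bool)
    if mac.shape != img.shape:
        raise ValidationError("macrophage mask shape must match the grid")
    if not mac.any():
        raise ValidationError("macrophage mask is empty")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be strictly increasing, length >= 2")
    dist = ndimage.distance_transform_edt(~mac, sampling=grid.voxel_size)
    outside = ~mac
    d, v = dist[outside], img[outside]
    means = np.full(edges.size - 1, np.nan)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (d >= lo) & (d < hi)
        if sel.any():
            means[i] = v[sel].mean()
    near_sel = (d > 0) & (d < near_cut)
    far_sel = d >= edges[-2]
    flag = None
    if far_sel.any() and near_sel.any():
        far_mean = v[far_sel].mean()
        fold = float(v[near_sel].mean() / far_mean) if far_mean != 0 else float("nan")
        if far_mean == 0:
            flag = "zero far-field mean; fold undefined"
    else:
        fold = float("nan")
        flag = "empty near or far bin; fold undefined"
    return ProximityProfile(
        bin_edges=edges, mean_intensity=means, fold_vs_far=fold, near_cut=near_cut, flag=flag
    )


def neighbour_damage_contrast(
    cells: pd.DataFrame,
    near_cut: float = DEFAULT_NEAR_CUT,
    sample_column: str = "sample_id",
) -> dict:
    """Damage contrast between macrophage-adjacent and distant cells.

    Cells are split at ``near_cut`` on their distance to the nearest
    macrophage; per-sample mean puncta counts for both strata are
    compared by a matched two-tailed t-test over sample-level means.
    With a single sample only the descriptive contrast is reported.
    """
    for col in ("puncta_count", "dist_to_macrophage_um"):
        if col not in cells.columns:
            raise ValidationError(f"cell table missing column {col!r}")
    df = cells.copy()
    if sample_column not in df.columns:
        df[sample_column] = 0
    near = df["dist_to_macrophage_um"] < near_cut
    if not near.any() or near.all():
        raise ValidationError("need both near and far cells for the contrast")
    per_sample = (
        df.assign(near=near)
        .groupby([sample_column, "near"])["puncta_count"]
        .mean()
        .unstack("near")
        .rename(columns={True: "near_mean", False: "far_mean"})
        .dropna()
    )
    out: dict = {
        "near_cut_um": near_cut,
        "n_samples": int(len(per_sample)),
        "near_mean": float(df.loc[near, "puncta_count"].mean()),
        "far_mean": float(df.loc[~near, "puncta_count"].mean()),
    }
    out["ratio_near_far"] = (
        out["near_mean"] / out["far_mean"] if out["far_mean"] != 0 else float("nan")
    )
    out["difference"] = out["near_mean"] - out["far_mean"]
    if len(per_sample) >= 2:
        t, p = stats.ttest_rel(per_sample["near_mean"], per_sample["far_mean"])
        out["paired_t"] = float(t)
        out["paired_p"] = float(p)
        out["flag"] = None
    else:
        out["paired_t"] = float("nan")
        out["paired_p"] = float("nan")
        out["flag"] = "single sample; paired test not available"
    return out
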