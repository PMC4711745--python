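"""End-to-end reproducible runs: simulate -> preprocess -> segment ->
quantify -> spatial statistics -> report.

A run is driven by a single :class:`RunConfig` (one YAML document); the
seed and every parameter are echoed into the machine-readable report,
and rerunning with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .cytometry import (
    DEFAULT_DAMAGE_THRESHOLD,
    DEFAULT_MFI_RADIUS,
    PunctaParams,
    SegmentationParams,
    build_cell_table,
    dose_damage_association,
    macrophage_mask,
    segment_nuclei,
)
from .model import ValidationError
from .pk import extract_vessel_series, fit_decay, subtract_background, vessel_mask_from_tracer
from .spatial import (
    DEFAULT_NEAR_CUT,
    DEFAULT_ROI_SIZE,
    manders_coloc,
    neighbour_damage_contrast,
    pearson_coloc,
    proximity_profile,
    spatial_cv,
)
from .synth import SynthConfig, generate_timelapse, generate_tissue

ALL_STAGES = ("simulate", "pkfit", "cytometry", "spatial")


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    stages: tuple[str, ...] = ALL_STAGES
    synth: SynthConfig = field(default_factory=SynthConfig)
    timelapse: SynthConfig | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    puncta: PunctaParams = field(default_factory=PunctaParams)
    mfi_radius: float = DEFAULT_MFI_RADIUS
    damage_threshold: int = DEFAULT_DAMAGE_THRESHOLD
    cv_roi_size: float = DEFAULT_ROI_SIZE
    near_cut: float = DEFAULT_NEAR_CUT
    proximity_bin_edges: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 45)
    out_dir: str = "ivcyto_run"
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValidationError(f"unknown stage {s!r}; valid: {ALL_STAGES}")
        self.stages = tuple(self.stages)
        if self.timelapse is None:
            self.timelapse = SynthConfig.timelapse_default(seed=self.seed)
        if self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig.from_dict(kwargs["synth"])
        if kwargs.get("timelapse") is not None:
            kwargs["timelapse"] = SynthConfig.from_dict(kwargs["timelapse"])
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "puncta" in kwargs:
            kwargs["puncta"] = PunctaParams(**kwargs["puncta"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        puncta = dataclasses.asdict(self.puncta)
        puncta["spot_sigma_range"] = list(puncta["spot_sigma_range"])
        return {
            "stages": list(self.stages),
            "synth": self.synth.to_dict(),
            "timelapse": self.timelapse.to_dict() if self.timelapse else None,
            "segmentation": dataclasses.asdict(self.segmentation),
            "puncta": puncta,
            "mfi_radius": self.mfi_radius,
            "damage_threshold": self.damage_threshold,
            "cv_roi_size": self.cv_roi_size,
            "near_cut": self.near_cut,
            "proximity_bin_edges": list(self.proximity_bin_edges),
            "out_dir": self.out_dir,
            "seed": self.seed,
        }


def _provenance(op: str, **params) -> dict:
    return {"operation": op, "parameters": params}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the report.

    Outputs under ``config.out_dir``: the synthetic tissue TIFF with its
    sidecar, the ground-truth CSV/JSON, the per-cell CSV table, the
    decay-fit / co-localization / heterogeneity / proximity JSON
    documents, and ``report.json`` echoing every parameter and the seed.
    A stage failure aborts with the failing stage named; outputs written
    so far are kept alongside a ``FAILED`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "seed": config.seed, "results": {}}
    grid = gt = None
    current = None
    try:
        if "simulate" in config.stages:
            current = "simulate"
            grid, gt = generate_tissue(config.synth)
            io.write_volume(grid, out / "tissue.tif")
            gt.write(out / "ground_truth_cells.csv", out / "ground_truth.json")
            report["results"]["simulate"] = {
                "n_cells": gt.n_cells,
                "n_macrophages": gt.n_macrophages,
                "provenance": _provenance("generate_tissue", **config.synth.to_dict()),
            }

        if "pkfit" in config.stages:
            current = "pkfit"
            tl_grid, tl_gt = generate_timelapse(config.timelapse)
            vessels = vessel_mask_from_tracer(tl_grid)
            corrected, flags = subtract_background(tl_grid, [0])
            post = ~flags
            times = corrected.frame_times[post] - corrected.frame_times[post][0]
            fits = {}
            for channel in ("vehicle", "payload"):
                _, series = extract_vessel_series(corrected, vessels, channel)
                fit = fit_decay(series[post], times)
                fits[channel] = fit.to_dict()
            io.write_json(fits, out / "decay_fits.json")
            report["results"]["pkfit"] = {
                **{c: {"t_half_min": fits[c]["t_half_min"], "r_squared": fits[c]["r_squared"]} for c in fits},
                "provenance": _provenance(
                    "fit_decay", timelapse=config.timelapse.to_dict(), background_frames=[0]
                ),
            }

        if "cytometry" in config.stages:
            current = "cytometry"
            if grid is None:
                raise PipelineError("cytometry requires the simulate stage (no input volume)")
            nuclei = segment_nuclei(grid, config.segmentation)
            cells = build_cell_table(
                grid,
                nuclei=nuclei,
                puncta_params=config.puncta,
                mfi_radius=config.mfi_radius,
                damage_threshold=config.damage_threshold,
            )
            io.write_cell_table(cells, out / "cells.csv")
            assoc = dose_damage_association(cells, config.damage_threshold)
            io.write_json(assoc, out / "dose_damage.json")
            report["results"]["cytometry"] = {
                "n_nuclei": int(nuclei.n_labels),
                "high_damage_fraction": float(
                    (cells["puncta_count"] >= config.damage_threshold).mean()
                ) if len(cells) else 0.0,
                "payload_ratio_high_low": assoc["payload"]["ratio_high_low"],
                "anova_p_payload": assoc["payload"]["anova_p"],
                "provenance": _provenance(
                    "build_cell_table",
                    segmentation=dataclasses.asdict(config.segmentation),
                    puncta=dataclasses.asdict(config.puncta),
                    mfi_radius_um=config.mfi_radius,
                    damage_threshold=config.damage_threshold,
                ),
            }

        if "spatial" in config.stages:
            current = "spatial"
            if grid is None:
                raise PipelineError("spatial requires the simulate stage (no input volume)")
            mac = macrophage_mask(grid)
            coloc = pearson_coloc(grid, "vehicle", "payload")
            manders = manders_coloc(grid, "vehicle", "payload", mask=mac if mac.any() else None)
            cv_vehicle = spatial_cv(grid, "vehicle", config.cv_roi_size)
            cv_payload = spatial_cv(grid, "payload", config.cv_roi_size)
            spatial_doc: dict = {
                "pearson": coloc.to_dict(),
                "manders": manders.to_dict(),
                "cv_vehicle": cv_vehicle.to_dict(),
                "cv_payload": cv_payload.to_dict(),
            }
            if mac.any():
                prox = proximity_profile(
                    grid, "payload", mac, config.proximity_bin_edges, config.near_cut
                )
                spatial_doc["proximity_payload"] = prox.to_dict()
                cells_path = out / "cells.csv"
                if cells_path.exists():
                    cells = io.read_cell_table(cells_path)
                    finite = cells[np.isfinite(cells["dist_to_macrophage_um"])]
                    if len(finite) and (finite["dist_to_macrophage_um"] < config.near_cut).any() \
                            and (finite["dist_to_macrophage_um"] >= config.near_cut).any():
                        spatial_doc["neighbour_damage"] = neighbour_damage_contrast(
                            finite, config.near_cut
                        )
            spatial_doc["provenance"] = _provenance(
                "spatial_statistics",
                cv_roi_size_um=config.cv_roi_size,
                near_cut_um=config.near_cut,
                proximity_bin_edges_um=list(config.proximity_bin_edges),
            )
            io.write_json(spatial_doc, out / "spatial.json")
            summary = {
                "pearson_rho": coloc.pearson_rho,
                "cv_vehicle": cv_vehicle.cv,
                "cv_payload": cv_payload.cv,
            }
            if "proximity_payload" in spatial_doc:
                summary["proximity_fold_vs_far"] = spatial_doc["proximity_payload"]["fold_vs_far"]
            report["results"]["spatial"] = summary
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {current}\nerror: {err}\n")
        raise PipelineError(f"stage {current!r} failed: {err}") from err

    io.write_json(report, out / "report.json")
    return report
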