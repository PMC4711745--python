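"""Shared fixtures: expensive synthetic volumes are session-scoped."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage
from scipy.spatial import cKDTree

import ivcyto as iv

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_tissue():
    """The default 200-cell tumour snapshot (seed 42) with ground truth."""
    return iv.generate_tissue(iv.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def noisefree_tissue():
    """Same configuration without imaging noise."""
    cfg = iv.SynthConfig(seed=42, photon_scale=float("inf"), read_noise_sd=0.0)
    return iv.generate_tissue(cfg)


@pytest.fixture(scope="session")
def default_analysis(default_tissue):
    """Segmentation, puncta counts and cell table for the default tissue."""
    grid, gt = default_tissue
    nuclei = iv.segment_nuclei(grid)
    counts = iv.detect_puncta(grid, nuclei)
    cells = iv.build_cell_table(grid, nuclei=nuclei)
    return nuclei, counts, cells


@pytest.fixture(scope="session")
def cohort():
    """Four replicate tumour samples of 250 cells each (seeds 101-104)."""
    cfg_base = dict(volume_shape=(64, 288, 288), n_cells=250)
    tables = []
    truths = []
    for k, seed in enumerate((101, 102, 103, 104)):
        grid, gt = iv.generate_tissue(iv.SynthConfig(seed=seed, **cfg_base))
        cells = iv.build_cell_table(grid)
        cells["sample_id"] = k
        tables.append(cells)
        truths.append(gt)
    return pd.concat(tables, ignore_index=True), truths


def match_to_ground_truth(nuclei, gt, voxel_size):
    """1-to-1 match segmented labels to ground-truth cells by centroid.

    A truth cell is matched when the nearest segmented centroid lies
    within one nuclear radius.  Returns (matched_mask, label_indices).
    """
    n = nuclei.n_labels
    if n == 0:
        return np.zeros(gt.n_cells, dtype=bool), np.zeros(0, dtype=int)
    cents = (
        np.array(
            ndimage.center_of_mass(
                np.ones_like(nuclei.labels), nuclei.labels, range(1, n + 1)
            )
        )
        * np.asarray(voxel_size)
    )
    d, idx = cKDTree(cents).query(gt.cell_centroids)
    matched = d <= gt.cell_radii
    return matched, idx
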