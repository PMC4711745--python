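"""Population-level uptake accounting and small shared formulas.

Given flow-style per-population summaries (cell fraction, raw MFI,
control MFI) the share of total drug uptake attributable to each
population is the prevalence-weighted net MFI:

    uptake_fraction_k = f_k m_k / sum_j f_j m_j

with net MFI m = max(raw - control, 0).  Also here: percent decrease,
the spherical tumour volume formula V = 4/3 pi r^3 with r averaged from
caliper measurements, and the platinum mass-fraction to molarity
conversion (ng Pt per mg tissue -> μM).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ValidationError

#: Standard atomic weight of platinum, g/mol.
PT_ATOMIC_WEIGHT = 195.084

#: μM per (ng Pt / mg tissue), assuming tissue density 1 g/ml.
UM_PER_NG_PER_MG = 1.0e3 / PT_ATOMIC_WEIGHT  # = 5.126


@dataclass
class PopulationUptake:
    """One immunologically defined population's uptake summary (one channel)."""

    name: str
    cell_fraction: float
    raw_mfi: float
    control_mfi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise ValidationError("cell_fraction must be in [0, 1]")
        if self.raw_mfi < 0 or self.control_mfi < 0:
            raise ValidationError("MFIs must be >= 0")

    @property
    def net_mfi(self) -> float:
        return net_population_mfi(self.raw_mfi, self.control_mfi)


def net_population_mfi(raw_mfi: float, control_mfi: float) -> float:
    """Background-subtracted population MFI, clipped at zero."""
    if raw_mfi < 0 or control_mfi < 0:
        raise ValidationError("MFIs must be >= 0")
    return max(raw_mfi - control_mfi, 0.0)


def uptake_fractions(populations: list[PopulationUptake]) -> dict[str, float]:
    """Prevalence-weighted share of total uptake per population.

    The fractions sum to one over the included populations and are
    invariant under a common rescaling of all net MFIs.
    """
    if not populations:
        raise ValidationError("no populations given")
    total_fraction = sum(p.cell_fraction for p in populations)
    if total_fraction > 1.0 + 1e-9:
        raise ValidationError(f"cell fractions sum to {total_fraction:.3f} > 1")
    weights = np.array([p.cell_fraction * p.net_mfi for p in populations])
    total = weights.sum()
    if total <= 0:
        raise ValidationError("all-zero weighted uptake; fractions undefined")
    return {p.name: float(w / total) for p, w in zip(populations, weights)}


def percent_decrease(reference: float, depleted: float) -> float:
    """Percent decrease from a reference value: 100 (ref - x) / ref."""
    if reference <= 0:
        raise ValidationError("reference must be > 0")
    return 100.0 * (reference - depleted) / reference


def pt_mass_to_molar(pt_mass_per_tissue: float) -> float:
    """Convert ng Pt per mg tissue to μM (tissue density 1 g/ml)."""
    if pt_mass_per_tissue < 0:
        raise ValidationError("mass fraction must be >= 0")
    return pt_mass_per_tissue * UM_PER_NG_PER_MG


@dataclass
class TumourVolumeEstimate:
    caliper_measurements: tuple[float, float, float, float]  # mm, diameters
    r: float  # mm
    V: float  # mm³


def tumour_volume(calipers, calipers_are_diameters: bool = True) -> TumourVolumeEstimate:
    """Spherical tumour volume V = 4/3 pi r^3, r averaged from 4 calipers.

    Caliper readings are interpreted as diameters by default
    (r = mean / 2); set ``calipers_are_diameters=False`` to average them
    as radii directly.
    """
    c = [float(x) for x in calipers]
    if len(c) != 4:
        raise ValidationError("exactly 4 caliper measurements required")
    if any(x < 0 for x in c):
        raise ValidationError("caliper measurements must be >= 0")
    r = float(np.mean(c)) / (2.0 if calipers_are_diameters else 1.0)
    return TumourVolumeEstimate(tuple(c), r, (4.0 / 3.0) * np.pi * r**3)


# ---------------------------------------------------------------------------
# CSV interface

POPULATION_COLUMNS = (
    "name",
    "cell_fraction",
    "raw_mfi_vehicle",
    "control_mfi_vehicle",
    "raw_mfi_payload",
    "control_mfi_payload",
)


def read_population_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"population table missing columns: {missing}")
    return df


def account_uptake(df: pd.DataFrame) -> dict:
    """Per-channel uptake fractions from a population summary table."""
    out: dict = {"populations": list(df["name"])}
    for channel in ("vehicle", "payload"):
        pops = [
            PopulationUptake(
                name=row["name"],
                cell_fraction=float(row["cell_fraction"]),
                raw_mfi=float(row[f"raw_mfi_{channel}"]),
                control_mfi=float(row[f"control_mfi_{channel}"]),
            )
            for _, row in df.iterrows()
        ]
        out[channel] = {
            "net_mfi": {p.name: p.net_mfi for p in pops},
            "uptake_fraction": uptake_fractions(pops),
        }
    return out
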