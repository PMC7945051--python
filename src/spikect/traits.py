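"""Spike-, spikelet- and grain-level morphometric traits and validation.

Trait definitions follow the field's conventions: spike length is the axial
(z) distance between the centroids of the top and bottom grains, spikelet
density is spikelets per centimetre of spike length, and per-spikelet
profiles are reported bottom-to-top.  Validation against manual counts uses
the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spikelet import Grain, Spikelet


@dataclass(frozen=True)
class SpikeTraits:
    grain_count: int
    total_grain_volume_mm3: float
    mean_grain_volume_mm3: float
    spike_length_mm: float
    spikelet_count: int
    spikelet_density_per_cm: float
    mean_grains_per_spikelet: float
    mean_volume_per_spikelet_mm3: float

    def __post_init__(self) -> None:
        # internal consistency: means times counts reproduce the totals
        if not np.isclose(
            self.mean_grain_volume_mm3 * self.grain_count,
            self.total_grain_volume_mm3,
            rtol=1e-12,
            atol=1e-12,
        ):
            raise ValueError("mean_grain_volume * grain_count != total volume")

    def to_dict(self) -> dict:
        return {
            "grain_count": self.grain_count,
            "total_grain_volume_mm3": self.total_grain_volume_mm3,
            "mean_grain_volume_mm3": self.mean_grain_volume_mm3,
            "spike_length_mm": self.spike_length_mm,
            "spikelet_count": self.spikelet_count,
            "spikelet_density_per_cm": self.spikelet_density_per_cm,
            "mean_grains_per_spikelet": self.mean_grains_per_spikelet,
            "mean_volume_per_spikelet_mm3": self.mean_volume_per_spikelet_mm3,
        }


def spike_length(grains: list[Grain]) -> float:
    """Axial distance (mm) between the top and bottom grain centroids."""
    if len(grains) < 2:
        raise ValueError("spike length needs at least 2 grains")
    z = [g.z_mm for g in grains]
    return float(max(z) - min(z))


def spike_report(grains: list[Grain], spikelets: list[Spikelet]) -> SpikeTraits:
    """Whole-spike morphometric summary."""
    if not grains:
        raise ValueError("empty grain list")
    _check_partition(grains, spikelets)
    volumes = np.array([g.volume_mm3 for g in grains])
    length_mm = spike_length(grains)
    n_spikelets = len(spikelets)
    density = n_spikelets / (length_mm / 10.0) if length_mm > 0 else float("nan")
    return SpikeTraits(
        grain_count=len(grains),
        total_grain_volume_mm3=float(volumes.sum()),
        mean_grain_volume_mm3=float(volumes.sum()) / len(grains),
        spike_length_mm=length_mm,
        spikelet_count=n_spikelets,
        spikelet_density_per_cm=density,
        mean_grains_per_spikelet=len(grains) / n_spikelets,
        mean_volume_per_spikelet_mm3=float(volumes.sum()) / n_spikelets,
    )


def spikelet_profile(grains: list[Grain], spikelets: list[Spikelet]) -> pd.DataFrame:
    """Per-spikelet rows bottom-to-top; volume fractions sum to 1."""
    if not spikelets:
        raise ValueError("empty spikelet partition")
    _check_partition(grains, spikelets)
    total = sum(s.total_volume_mm3 for s in spikelets)
    if total <= 0:
        raise ValueError("total grain volume must be positive")
    frame = pd.DataFrame(
        {
            "spikelet_index": [s.index for s in spikelets],
            "grain_count": [s.grain_count for s in spikelets],
            "mean_grain_volume_mm3": [s.mean_volume_mm3 for s in spikelets],
            "total_volume_mm3": [s.total_volume_mm3 for s in spikelets],
        }
    ).sort_values("spikelet_index", ignore_index=True)
    frame["volume_fraction_of_spike"] = frame["total_volume_mm3"] / total
    return frame


def _check_partition(grains: list[Grain], spikelets: list[Spikelet]) -> None:
    grain_ids = {g.id for g in grains}
    assigned: list[int] = []
    for s in spikelets:
        assigned.extend(s.grain_ids)
    if len(assigned) != len(set(assigned)) or set(assigned) != grain_ids:
        raise ValueError("spikelets do not partition the grain set")


def pearson_r2(x, y) -> float:
    """Squared Pearson product-moment correlation of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def validate_against_manual(
    ct_table: pd.DataFrame,
    manual_table: pd.DataFrame,
    on: str = "spike_id",
) -> pd.DataFrame:
    """Compare CT-derived counts with manual reference counts per spike.

    Both tables need a ``spike_id`` column; count traits present in both
    (``grain_count``, ``spikelet_count``, ``mean_grains_per_spikelet``) are
    compared by r^2 and mean signed difference (CT minus manual).  If the
    manual table carries ``grain_mass_g`` and the CT table
    ``total_grain_volume_mm3``, their correlation is reported as the
    ``volume_vs_mass`` row (no signed difference: units differ).
    """
    for name, table in (("ct", ct_table), ("manual", manual_table)):
        if on not in table.columns:
            raise ValueError(f"{name} table lacks the '{on}' column")
    merged = ct_table.merge(manual_table, on=on, suffixes=("_ct", "_manual"))
    if len(merged) != len(ct_table) or len(merged) != len(manual_table):
        raise ValueError("spike identifiers do not match between the two tables")
    rows = []
    for trait in ("grain_count", "spikelet_count", "mean_grains_per_spikelet"):
        ct_col, man_col = f"{trait}_ct", f"{trait}_manual"
        if ct_col in merged.columns and man_col in merged.columns:
            ct = merged[ct_col].to_numpy(dtype=float)
            man = merged[man_col].to_numpy(dtype=float)
            rows.append(
                {
                    "trait": trait,
                    "r2": pearson_r2(ct, man),
                    "mean_signed_difference": float(np.mean(ct - man)),
                }
            )
    vol_col = "total_grain_volume_mm3"
    vol = merged.get(f"{vol_col}_ct", merged.get(vol_col))
    mass = merged.get("grain_mass_g_manual", merged.get("grain_mass_g"))
    if vol is not None and mass is not None:
        rows.append(
            {
                "trait": "volume_vs_mass",
                "r2": pearson_r2(vol.to_numpy(float), mass.to_numpy(float)),
                "mean_signed_difference": float("nan"),
            }
        )
    if not rows:
        raise ValueError("no comparable trait columns found")
    return pd.DataFrame(rows)
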