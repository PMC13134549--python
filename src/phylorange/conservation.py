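"""Range areas, contraction, complete-loss classification, protected overlap.

Areas are summed over presence cells of the fine-resolution binary maps
using the spherical cell area R^2 * dlam * |sin(phi_top) - sin(phi_bot)|
(R = 6,371 km), so cell area depends only on the latitude band.
Contraction is (current - future) / current * 100: 100 means complete loss
of climatic suitability, negative values are range expansions.  Genus
summaries average per-species contraction within the genus parsed from the
leading token of the species identifier.  Protected-area overlap is the
area-weighted percentage of a range inside the mask.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .diversity import PresenceAbsenceMatrix
from .grids import RegionMask, require_aligned
from .sdm import BinaryRangeMap

__all__ = [
    "UndefinedBaselineError",
    "range_area_km2",
    "contraction_percent",
    "build_conservation_table",
    "classify_loss",
    "LossClassification",
    "genus_summary",
    "protected_overlap",
    "zonal_richness",
    "genus_of",
]


class UndefinedBaselineError(ValueError):
    """Contraction is undefined for a zero current area."""


def range_area_km2(range_map: BinaryRangeMap) -> float:
    """Spherical area (km^2) of the presence cells."""
    band_areas = range_map.spec.cell_area_km2()
    cells_per_row = range_map.presence.sum(axis=1)
    return float(np.dot(band_areas, cells_per_row))


def contraction_percent(current_area: float, future_area: float) -> float:
    """(current - future) / current * 100; capped above at 100.

    Unbounded below: a future range larger than twice the current one
    yields a contraction below -100 (a strong expansion).
    """
    if not current_area > 0:
        raise UndefinedBaselineError("current area must be > 0")
    return min(100.0, (current_area - future_area) / current_area * 100.0)


def genus_of(species_id: str) -> str:
    """Genus = leading token of the species identifier."""
    return species_id.replace("_", " ").split()[0]


def build_conservation_table(
    current_ranges: dict[str, BinaryRangeMap],
    future_ranges: dict[str, dict[str, BinaryRangeMap]],
    protected: RegionMask | None = None,
) -> pd.DataFrame:
    """Tidy per-species x per-scenario accounting table.

    ``future_ranges`` maps scenario_id -> {species_id -> range}.  Columns:
    species, genus, scenario, current_area_km2, future_area_km2,
    contraction_percent, complete_loss, protected_percent (future range
    inside the protected mask; NaN when the future range is empty or no
    mask is given).
    """
    rows = []
    for scenario, ranges in future_ranges.items():
        for sid, fut in ranges.items():
            if sid not in current_ranges:
                continue
            cur_area = range_area_km2(current_ranges[sid])
            fut_area = range_area_km2(fut)
            if cur_area <= 0:
                continue
            contraction = contraction_percent(cur_area, fut_area)
            prot = (
                protected_overlap(fut, protected)
                if (protected is not None and fut_area > 0)
                else np.nan
            )
            rows.append(
                {
                    "species": sid,
                    "genus": genus_of(sid),
                    "scenario": scenario,
                    "current_area_km2": cur_area,
                    "future_area_km2": fut_area,
                    "contraction_percent": contraction,
                    "complete_loss": fut_area == 0.0,
                    "protected_percent": prot,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class LossClassification:
    lost_any: list[str]
    lost_all: list[str]

    @property
    def n_any(self) -> int:
        return len(self.lost_any)

    @property
    def n_all(self) -> int:
        return len(self.lost_all)


def classify_loss(
    table: pd.DataFrame,
    scenarios: list[str] | None = None,
    tolerance: float = 1e-9,
) -> LossClassification:
    """Species losing all climatic suitability under >=1 / all scenarios.

    ``table`` is the tidy conservation table (or anything with species,
    scenario, contraction_percent columns); complete loss in a scenario
    means contraction of 100%.
    """
    required = {"species", "scenario", "contraction_percent"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    scenarios = scenarios or sorted(table["scenario"].unique())
    wide = table.pivot_table(
        index="species", columns="scenario", values="contraction_percent"
    )
    missing = [s for s in scenarios if s not in wide.columns]
    if missing:
        raise ValueError(f"missing scenario column(s): {missing}")
    wide = wide[scenarios]
    lost = (wide - 100.0).abs() <= tolerance
    complete = lost.fillna(False)
    any_mask = complete.any(axis=1)
    all_mask = complete.all(axis=1) & wide.notna().all(axis=1)
    return LossClassification(
        lost_any=sorted(wide.index[any_mask]),
        lost_all=sorted(wide.index[all_mask]),
    )


def genus_summary(
    table: pd.DataFrame,
    scenario: str,
    include_complete_loss: bool = True,
) -> pd.DataFrame:
    """Unweighted mean per-species contraction within each genus, ranked.

    ``include_complete_loss=False`` drops 100%-contraction species before
    averaging (an alternative aggregation some summaries use).
    """
    sub = table[table["scenario"] == scenario].copy()
    if sub.empty:
        raise ValueError(f"no rows for scenario {scenario!r}")
    if "genus" not in sub.columns:
        sub["genus"] = sub["species"].map(genus_of)
    if not include_complete_loss:
        sub = sub[sub["contraction_percent"] < 100.0 - 1e-9]
    out = (
        sub.groupby("genus")["contraction_percent"]
        .agg(mean_contraction_percent="mean", n_species="size")
        .sort_values("mean_contraction_percent", ascending=False)
    )
    return out


def protected_overlap(range_map: BinaryRangeMap, protected: RegionMask) -> float:
    """Percentage of the range's area inside the protected mask."""
    require_aligned(range_map.spec, protected.spec)
    band_areas = range_map.spec.cell_area_km2()
    total = float(np.dot(band_areas, range_map.presence.sum(axis=1)))
    if total <= 0:
        warnings.warn(f"{range_map.species_id}: empty range; protected overlap undefined")
        return float("nan")
    inside = float(np.dot(band_areas, (range_map.presence & protected.mask).sum(axis=1)))
    return inside / total * 100.0


def zonal_richness(
    pam: PresenceAbsenceMatrix,
    regions: list[RegionMask],
) -> pd.DataFrame:
    """Species counts per region (a species counts if any presence cell of
    the coarse PAM falls inside the region's raster).

    Region masks live on a fine grid; a coarse PAM cell intersects a region
    when any fine cell inside it is covered.  Returns a DataFrame with
    region, n_species and the species list.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    res = pam.resolution_deg
    cell_lon = pam.cells["lon"].to_numpy()
    cell_lat = pam.cells["lat"].to_numpy()
    rows = []
    for region in regions:
        spec = region.spec
        rmask, cmask = np.nonzero(region.mask)
        if len(rmask) == 0:
            rows.append({"region": region.name, "n_species": 0, "species": []})
            continue
        lon_f = spec.lon_centers()[cmask]
        lat_f = spec.lat_centers()[rmask]
        covered = set(
            zip(
                np.floor(lon_f / res).astype(int).tolist(),
                np.floor(lat_f / res).astype(int).tolist(),
            )
        )
        ci = np.floor(cell_lon / res).astype(int)
        cj = np.floor(cell_lat / res).astype(int)
        in_region = np.array([(a, b) in covered for a, b in zip(ci, cj)])
        if not in_region.any():
            warnings.warn(f"region {region.name!r} intersects no occupied PAM cell")
            rows.append({"region": region.name, "n_species": 0, "species": []})
            continue
        present = pam.matrix.to_numpy(dtype=bool)[in_region].any(axis=0)
        species = [s for s, p in zip(pam.species, present) if p]
        rows.append({"region": region.name, "n_species": len(species), "species": species})
    return pd.DataFrame(rows)
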