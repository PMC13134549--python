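"""Occurrence-record validation and accessible-area (M) construction.

Records are snapped to climate-grid cell centers for all raster work; the
stored coordinates are never modified.  The accessible area M — the region
a species could plausibly reach, which bounds model calibration and
pseudo-absence sampling — is the union of great-circle disks of a fixed
radius (default 500 km) around the species' validated records.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .grids import ClimateGrid, GridSpec, haversine_km

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "lon", "lat", "iucn_category")


class NoRecordsError(ValueError):
    """A species has no valid records where at least one is required."""


@dataclasses.dataclass
class ValidationResult:
    """Clean records plus an audit trail of what was dropped and why."""

    records: pd.DataFrame
    dropped: pd.DataFrame  # original rows + 'reason' column
    category_counts: dict[str, int]

    @property
    def n_valid(self) -> int:
        return int(len(self.records))


@dataclasses.dataclass
class AccessibleArea:
    """Boolean raster of the accessible area M for one species."""

    species_id: str
    spec: GridSpec
    mask: np.ndarray
    buffer_km: float

    def __post_init__(self) -> None:
        self.mask = self.mask.astype(bool)


def validate_records(raw: pd.DataFrame, grid: ClimateGrid) -> ValidationResult:
    """Validate, filter and deduplicate occurrence records against a grid.

    Drops (with a per-row reason): coordinates outside [-180, 180] x
    [-90, 90]; points off the climate grid; points on no-data cells; and
    all but one record per (species, grid cell).  The input is never
    mutated; validation is idempotent.
    """
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    if raw.empty:
        raise ValueError("raw occurrence set is empty")
    df = raw.reset_index(drop=True).copy()
    reason = pd.Series("", index=df.index, dtype=object)

    in_range = df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    reason[~in_range] = "coordinate out of range"

    row, col = grid.spec.index_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    on_grid = (row >= 0) & (col >= 0)
    reason[in_range & ~on_grid] = "off climate grid"

    valid_mask = grid.valid_mask()
    ok = in_range & on_grid
    on_data = np.zeros(len(df), dtype=bool)
    on_data[ok.to_numpy()] = valid_mask[row[ok.to_numpy()], col[ok.to_numpy()]]
    reason[ok & ~on_data] = "no-data climate cell"

    keep = reason == ""
    cell_id = pd.Series(-1, index=df.index, dtype=int)
    cell_id[keep] = row[keep.to_numpy()] * grid.spec.n_cols + col[keep.to_numpy()]
    dup = keep & df.assign(_cell=cell_id).duplicated(subset=["species", "_cell"])
    reason[dup] = "duplicate record in grid cell"
    keep = reason == ""

    clean = df[keep].reset_index(drop=True)
    dropped = df[~keep].assign(reason=reason[~keep].to_numpy()).reset_index(drop=True)
    if clean.empty:
        warnings.warn("all occurrence records were dropped during validation")
    for why, n in dropped["reason"].value_counts().items():
        logger.info("validate_records: dropped %d record(s): %s", n, why)
    counts = clean["iucn_category"].value_counts().to_dict()
    return ValidationResult(records=clean, dropped=dropped, category_counts={k: int(v) for k, v in counts.items()})


def occurrence_cells(records: pd.DataFrame, spec: GridSpec) -> np.ndarray:
    """Unique (row, col) cell indices occupied by the given records."""
    row, col = spec.index_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    ok = (row >= 0) & (col >= 0)
    cells = np.unique(np.stack([row[ok], col[ok]], axis=1), axis=0)
    return cells


def build_accessible_area(
    species_records: pd.DataFrame,
    grid: ClimateGrid,
    buffer_km: float = 500.0,
) -> AccessibleArea:
    """Union of great-circle disks of radius ``buffer_km`` around each record.

    Distances are measured between cell centers (records snapped to their
    cell) with the haversine formula on a 6,371 km sphere, so a zero buffer
    yields exactly the occupied cells.  The mask always covers every
    occurrence cell.
    """
    if species_records.empty:
        raise NoRecordsError("species has no records; cannot build accessible area")
    sids = species_records["species"].unique()
    if len(sids) != 1:
        raise ValueError("build_accessible_area expects records of a single species")
    spec = grid.spec
    cells = occurrence_cells(species_records, spec)
    if len(cells) == 0:
        raise NoRecordsError("no record falls on the climate grid")
    lon_c, lat_c = spec.center_mesh()
    occ_lon = spec.lon_centers()[cells[:, 1]]
    occ_lat = spec.lat_centers()[cells[:, 0]]
    mask = np.zeros(spec.shape, dtype=bool)
    for olon, olat in zip(occ_lon, occ_lat):
        mask |= haversine_km(lon_c, lat_c, olon, olat) <= buffer_km
    mask[cells[:, 0], cells[:, 1]] = True  # guarantee occurrence cells
    return AccessibleArea(species_id=str(sids[0]), spec=spec, mask=mask, buffer_km=buffer_km)
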