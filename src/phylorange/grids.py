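"""Lightweight geographic rasters on a regular lon/lat grid.

Conventions used everywhere in the package: geographic WGS84-style
longitude/latitude in decimal degrees, cell-center registration, row 0 is
the northernmost row, column 0 the westernmost column.  Raster layers are
plain ``numpy`` float arrays; missing data is ``NaN``.  Text I/O uses the
ESRI ASCII grid format so every artifact on disk is human-readable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

EARTH_RADIUS_KM = 6371.0


class GridMismatchError(ValueError):
    """Two rasters do not share the same grid geometry."""


class InvalidExtentError(ValueError):
    """A degenerate (zero-width or inverted) geographic extent."""


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat raster (cell-center registration).

    Parameters
    ----------
    west, north:
        Outer edges of the north-west corner cell, in degrees.
    n_rows, n_cols:
        Grid shape; row 0 is the northernmost row.
    cellsize:
        Cell side length in degrees (square cells).
    """

    west: float
    north: float
    n_rows: int
    n_cols: int
    cellsize: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cellsize <= 0:
            raise InvalidExtentError(
                f"degenerate grid: {self.n_rows}x{self.n_cols} @ {self.cellsize}"
            )

    @classmethod
    def from_extent(
        cls, west: float, south: float, east: float, north: float, resolution_arcmin: float
    ) -> "GridSpec":
        if not (east > west and north > south and resolution_arcmin > 0):
            raise InvalidExtentError(
                f"degenerate extent ({west}, {south}, {east}, {north})"
            )
        cellsize = resolution_arcmin / 60.0
        n_cols = int(round((east - west) / cellsize))
        n_rows = int(round((north - south) / cellsize))
        if n_cols < 1 or n_rows < 1:
            raise InvalidExtentError("extent smaller than one cell")
        return cls(west=west, north=north, n_rows=n_rows, n_cols=n_cols, cellsize=cellsize)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cellsize

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cellsize

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell center."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points.

        Points outside the grid get index -1 in the offending dimension.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.cellsize).astype(int)
        row = np.floor((self.north - lat) / self.cellsize).astype(int)
        col = np.where((lon >= self.west) & (lon < self.east), col, -1)
        row = np.where((lat > self.south) & (lat <= self.north), row, -1)
        # points exactly on the east/south edge belong to the last cell
        col = np.where(lon == self.east, self.n_cols - 1, col)
        row = np.where(lat == self.south, self.n_rows - 1, row)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.index_of(lon, lat)
        return (row >= 0) & (col >= 0)

    def cell_area_km2(self) -> np.ndarray:
        """Spherical area of each latitude band's cells, shape (n_rows,).

        A = R^2 * dlam * |sin(phi_top) - sin(phi_bottom)| with R = 6371 km.
        """
        lat_top = np.deg2rad(self.north - np.arange(self.n_rows) * self.cellsize)
        lat_bot = lat_top - np.deg2rad(self.cellsize)
        dlam = np.deg2rad(self.cellsize)
        return EARTH_RADIUS_KM**2 * dlam * np.abs(np.sin(lat_top) - np.sin(lat_bot))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km.

    Broadcasts over numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclasses.dataclass
class ClimateGrid:
    """A stack of aligned climate layers tagged with a scenario label."""

    spec: GridSpec
    layers: dict[str, np.ndarray]
    scenario_id: str = "current"

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.spec.shape:
                raise GridMismatchError(
                    f"layer {name!r} has shape {arr.shape}, grid is {self.spec.shape}"
                )

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Cells with finite data in every layer."""
        mask = np.ones(self.spec.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def values_at(self, rows, cols, variables: Iterable[str] | None = None) -> np.ndarray:
        """Feature matrix (n_points, n_variables) sampled at cell indices."""
        variables = list(variables) if variables is not None else self.variables
        return np.column_stack([self.layers[v][rows, cols] for v in variables])

    def copy(self) -> "ClimateGrid":
        return ClimateGrid(self.spec, {k: v.copy() for k, v in self.layers.items()}, self.scenario_id)


@dataclasses.dataclass
class RegionMask:
    """A named boolean raster aligned to a grid (protected areas, ecoregions)."""

    name: str
    spec: GridSpec
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.spec.shape:
            raise GridMismatchError("mask shape does not match grid")
        self.mask = self.mask.astype(bool)

    def coverage_fraction(self) -> float:
        return float(self.mask.mean())


# ---------------------------------------------------------------------------
# Text raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, spec: GridSpec, array: np.ndarray) -> None:
    arr = np.asarray(array, dtype=float)
    if arr.shape != spec.shape:
        raise GridMismatchError("array shape does not match grid spec")
    out = np.where(np.isfinite(arr), arr, _NODATA)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.west}\n"
        f"yllcorner {spec.south}\n"
        f"cellsize {spec.cellsize}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value", _NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cellsize = header["cellsize"]
    spec = GridSpec(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * cellsize,
        n_rows=n_rows,
        n_cols=n_cols,
        cellsize=cellsize,
    )
    return spec, arr.reshape(n_rows, n_cols)


def mask_to_geojson(region: RegionMask, path: str | Path | None = None) -> dict:
    """Serialize a boolean raster mask as a GeoJSON MultiPolygon of cell boxes.

    Adjacent covered cells are dissolved with shapely before writing.
    """
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    spec = region.spec
    rows, cols = np.nonzero(region.mask)
    cells = [
        box(
            spec.west + c * spec.cellsize,
            spec.north - (r + 1) * spec.cellsize,
            spec.west + (c + 1) * spec.cellsize,
            spec.north - r * spec.cellsize,
        )
        for r, c in zip(rows, cols)
    ]
    geom = unary_union(cells) if cells else None
    feature = {
        "type": "Feature",
        "properties": {"name": region.name},
        "geometry": mapping(geom) if geom is not None else None,
    }
    collection = {"type": "FeatureCollection", "features": [feature]}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection


def require_aligned(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise GridMismatchError(f"grids differ: {a} vs {b}")
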