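"""Stacked ranges, taxonomic and Faith phylogenetic diversity, LOESS residuals.

Per-species binary range maps (fine 2.5-6 arc-minute grid) are stacked
into a coarse presence-absence matrix (PAM) on 0.5-degree cells anchored
at integer multiples of 0.5 in lon and lat.  From the PAM: taxonomic
diversity (TD) is the per-cell species count; Faith's phylogenetic
diversity (PD) is the summed branch length of the rooted subtree spanning
a cell's species (root path included by default — a single species
contributes its full root-to-tip distance); LOESS residuals of the PD~TD
relationship separate cells richer or poorer in evolutionary history than
their species count predicts; and the PD change between scenarios is the
per-cell percentage loss averaged over cells occupied today.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
import pandas as pd

from .grids import GridSpec
from .sdm import BinaryRangeMap

__all__ = [
    "PresenceAbsenceMatrix",
    "DiversityGrid",
    "ScenarioMismatchError",
    "UnmappedSpeciesError",
    "DegeneratePredictorError",
    "EmptyComparisonError",
    "stack_pam",
    "taxonomic_diversity",
    "faith_pd",
    "loess_residuals",
    "pd_change",
    "PDChangeSummary",
    "branch_incidence",
]


class ScenarioMismatchError(ValueError):
    """Range maps from different scenarios were mixed in one PAM."""


class UnmappedSpeciesError(KeyError):
    """PAM species missing from the phylogeny."""


class DegeneratePredictorError(ValueError):
    """All occupied cells share a single TD value; LOESS cannot fit."""


class EmptyComparisonError(ValueError):
    """No cell with positive current PD to compare against."""


@dataclasses.dataclass
class PresenceAbsenceMatrix:
    """Coarse cells x species binary matrix for one scenario.

    ``matrix`` is a DataFrame indexed by cell_id with one 0/1 column per
    species; ``cells`` carries the cell centers.  Only occupied cells are
    stored.
    """

    scenario_id: str
    resolution_deg: float
    cells: pd.DataFrame  # cell_id (index), lon, lat
    matrix: pd.DataFrame  # index cell_id, columns species, values {0,1}

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_cells(self) -> int:
        return len(self.matrix)


def _coarse_cell_ids(lon: np.ndarray, lat: np.ndarray, res: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer coarse-cell indices; cells anchored at multiples of ``res``."""
    ci = np.floor(lon / res).astype(int)
    cj = np.floor(lat / res).astype(int)
    return ci, cj


def stack_pam(
    ranges: list[BinaryRangeMap],
    coarse_resolution: float = 0.5,
) -> PresenceAbsenceMatrix:
    """Stack fine binary ranges onto the coarse PAM grid.

    A species is present in a coarse cell iff it is present in at least one
    constituent fine cell.  All ranges must share the fine grid and the
    scenario label.
    """
    if not ranges:
        raise ValueError("no range maps to stack")
    scen = ranges[0].scenario_id
    spec = ranges[0].spec
    for r in ranges:
        if r.scenario_id != scen:
            raise ScenarioMismatchError(f"{r.species_id}: scenario {r.scenario_id} != {scen}")
        if r.spec != spec:
            raise ScenarioMismatchError(f"{r.species_id}: fine grids differ")
    lon_centers = spec.lon_centers()
    lat_centers = spec.lat_centers()
    presence: dict[str, set[tuple[int, int]]] = {}
    for r in ranges:
        rows, cols = np.nonzero(r.presence)
        ci, cj = _coarse_cell_ids(lon_centers[cols], lat_centers[rows], coarse_resolution)
        presence[r.species_id] = set(zip(ci.tolist(), cj.tolist()))
    all_cells = sorted(set().union(*presence.values()) if presence else set())
    cell_ids = [f"{ci}_{cj}" for ci, cj in all_cells]
    res = coarse_resolution
    cells = pd.DataFrame(
        {
            "lon": [(ci + 0.5) * res for ci, _ in all_cells],
            "lat": [(cj + 0.5) * res for _, cj in all_cells],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    mat = pd.DataFrame(0, index=cells.index, columns=list(presence), dtype=np.int8)
    for sid, cellset in presence.items():
        ids = [f"{ci}_{cj}" for ci, cj in cellset]
        mat.loc[ids, sid] = 1
    return PresenceAbsenceMatrix(scen, coarse_resolution, cells, mat)


@dataclasses.dataclass
class DiversityGrid:
    """Per-coarse-cell diversity summaries for one scenario.

    ``table`` columns: lon, lat, td (species count), pd (My, optional),
    residual (My, optional); indexed by cell_id.
    """

    scenario_id: str
    resolution_deg: float
    table: pd.DataFrame

    def rasterize(self, column: str) -> tuple[GridSpec, np.ndarray]:
        """Paint one column onto a minimal coarse raster (NaN elsewhere)."""
        res = self.resolution_deg
        ci = np.floor(self.table["lon"].to_numpy() / res).astype(int)
        cj = np.floor(self.table["lat"].to_numpy() / res).astype(int)
        west = ci.min() * res
        north = (cj.max() + 1) * res
        spec = GridSpec(
            west=west,
            north=north,
            n_rows=int(cj.max() - cj.min() + 1),
            n_cols=int(ci.max() - ci.min() + 1),
            cellsize=res,
        )
        arr = np.full(spec.shape, np.nan)
        rows = cj.max() - cj
        cols = ci - ci.min()
        arr[rows, cols] = self.table[column].to_numpy()
        return spec, arr


def taxonomic_diversity(pam: PresenceAbsenceMatrix) -> DiversityGrid:
    """TD per coarse cell: the PAM row sum."""
    if pam.matrix.empty:
        raise ValueError("empty PAM")
    table = pam.cells.copy()
    table["td"] = pam.matrix.sum(axis=1).astype(int)
    return DiversityGrid(pam.scenario_id, pam.resolution_deg, table)


# ---------------------------------------------------------------------------
# Faith's PD
# ---------------------------------------------------------------------------

def branch_incidence(
    tree: dendropy.Tree, species: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, incidence) over the branches of ``tree``.

    ``incidence[b, s]`` is True when species ``s`` descends from branch
    ``b``.  Branches whose descendants include none of the named species
    (extra tips) are dropped, which restricts the tree to the minimal
    rooted subtree spanning the named species while keeping every
    root-to-tip path intact.  Branch lengths are in the tree's units (My
    for a dated tree).
    """
    labels = {t.label for t in tree.taxon_namespace}
    missing = [s for s in species if s not in labels]
    if missing:
        raise UnmappedSpeciesError(f"species missing from tree: {missing}")
    index = {s: i for i, s in enumerate(species)}
    vec_of: dict[int, np.ndarray] = {}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder_node_iter():
        vec = np.zeros(len(species), dtype=bool)
        if node.is_leaf():
            i = index.get(node.taxon.label if node.taxon else None)
            if i is not None:
                vec[i] = True
        else:
            for child in node.child_nodes():
                vec |= vec_of[id(child)]
        vec_of[id(node)] = vec
        if node.parent_node is not None and vec.any():
            length = node.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length")
            lengths.append(float(length))
            rows.append(vec)
    return np.asarray(lengths), np.vstack(rows)


def faith_pd(
    pam: PresenceAbsenceMatrix,
    tree: dendropy.Tree,
    include_root: bool = True,
) -> DiversityGrid:
    """Faith's PD per coarse cell.

    With ``include_root`` (default) PD is the total branch length of the
    minimal rooted subtree spanning the cell's species and the root, so a
    full assemblage scores the total tree length and a single species its
    root-to-tip distance.  With ``include_root=False`` the unrooted
    spanning subtree is used (single-species PD = 0).
    """
    species = pam.species
    lengths, inc = branch_incidence(tree, species)
    presence = pam.matrix.to_numpy(dtype=bool)  # cells x species
    hits = inc @ presence.T  # branches x cells: count of present descendants
    if include_root:
        used = hits > 0
    else:
        totals = presence.sum(axis=1)  # species per cell
        used = (hits > 0) & (hits < totals[np.newaxis, :])
    pd_values = lengths @ used
    grid = taxonomic_diversity(pam)
    grid.table["pd"] = pd_values
    return grid


# ---------------------------------------------------------------------------
# LOESS residuals
# ---------------------------------------------------------------------------

def _loess_1d(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Classic 1-D LOESS: tricube weights over the span-nearest neighbours,
    local weighted polynomial of the given degree, evaluated at each x."""
    n = len(x)
    k = min(n, max(degree + 1, int(np.ceil(span * n))))
    fitted_at: dict[float, float] = {}
    for x0 in np.unique(x):
        d = np.abs(x - x0)
        dk = np.sort(d)[k - 1]
        if dk == 0:
            fitted_at[x0] = float(np.mean(y[d == 0]))
            continue
        w = np.clip(1.0 - (d / dk) ** 3, 0.0, None) ** 3
        m = w > 0
        deg = min(degree, len(np.unique(x[m])) - 1)
        coef = np.polyfit(x[m], y[m], deg, w=np.sqrt(w[m]))
        fitted_at[x0] = float(np.polyval(coef, x0))
    return np.array([fitted_at[float(xi)] for xi in x])


def loess_residuals(
    grid: DiversityGrid,
    span: float = 0.75,
    degree: int = 2,
) -> DiversityGrid:
    """Residuals of a LOESS fit of PD on TD over occupied cells.

    Positive residuals mark cells holding more evolutionary history than
    their richness predicts (old, dispersed lineages); negative residuals
    mark cells dominated by recent speciation.  Requires >= 10 occupied
    cells and at least two distinct TD values.
    """
    if "pd" not in grid.table.columns:
        raise ValueError("grid lacks a 'pd' column; run faith_pd first")
    occupied = grid.table["td"] > 0
    x = grid.table.loc[occupied, "td"].to_numpy(dtype=float)
    y = grid.table.loc[occupied, "pd"].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError(f"need >= 10 occupied cells for LOESS, got {len(x)}")
    if np.unique(x).size < 2:
        raise DegeneratePredictorError("all occupied cells share one TD value")
    fit = _loess_1d(x, y, span=span, degree=degree)
    out = grid.table.copy()
    out.loc[occupied, "loess_fit"] = fit
    out.loc[occupied, "residual"] = y - fit
    return DiversityGrid(grid.scenario_id, grid.resolution_deg, out)


# ---------------------------------------------------------------------------
# PD change between scenarios
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PDChangeSummary:
    current_scenario: str
    future_scenario: str
    mean_loss_percent: float
    n_cells: int
    per_cell: pd.DataFrame  # cell_id, pd_current, pd_future, loss_percent


def pd_change(current: DiversityGrid, future: DiversityGrid) -> PDChangeSummary:
    """Mean per-cell percentage PD loss over cells occupied today.

    Cells present in the current grid but absent from the future grid count
    as complete loss (future PD = 0); negative losses (gains) are allowed.
    """
    for g in (current, future):
        if "pd" not in g.table.columns:
            raise ValueError("both grids need a 'pd' column")
    cur = current.table["pd"]
    fut = future.table["pd"].reindex(cur.index).fillna(0.0)
    base = cur > 0
    if not base.any():
        raise EmptyComparisonError("no cell with positive current PD")
    loss = (cur[base] - fut[base]) / cur[base] * 100.0
    per_cell = pd.DataFrame(
        {"pd_current": cur[base], "pd_future": fut[base], "loss_percent": loss}
    )
    return PDChangeSummary(
        current_scenario=current.scenario_id,
        future_scenario=future.scenario_id,
        mean_loss_percent=float(loss.mean()),
        n_cells=int(base.sum()),
        per_cell=per_cell,
    )
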