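"""EDGE prioritization: evolutionary distinctiveness x global endangerment.

Evolutionary Distinctiveness (ED, in My) apportions every branch of the
dated phylogeny equally among the tips descending from it ("fair
proportions"), so the ED values of all tips sum exactly to the total tree
length.  Global Endangerment (GE) maps the IUCN threat category to a
100-year extinction probability (configurable; defaults CR 0.999,
EN 0.667, VU 0.1).  The EDGE score is

    EDGE = ln(1 + ED) + GE * ln(2)

— strictly increasing in both components.  Scores are rasterized on the
coarse PAM grid with a per-cell aggregator (default: the maximum EDGE
among species present, locating individual evolutionarily unique,
highly threatened species; mean and sum are available).
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd

from .config import DEFAULT_GE_MAP
from .diversity import DiversityGrid, PresenceAbsenceMatrix, UnmappedSpeciesError

__all__ = [
    "UnmappedCategoryError",
    "evolutionary_distinctiveness",
    "ge_from_category",
    "edge_score",
    "species_scores",
    "map_edge",
]


class UnmappedCategoryError(KeyError):
    """An IUCN category absent from the configured GE map."""


def evolutionary_distinctiveness(tree: dendropy.Tree) -> pd.Series:
    """Fair-proportion ED per tip (same units as the branch lengths).

    ED(tip) = sum over branches on its root-to-tip path of
    branch_length / n_descendant_tips.  Summing ED over all tips
    reconstitutes the total branch length of the tree.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    # postorder: count descendant tips per node
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_tips = 1
        else:
            node._n_tips = sum(c._n_tips for c in node.child_nodes())
    # preorder: accumulate fair shares from the root down
    ed: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._fair = 0.0
        else:
            length = node.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length")
            node._fair = node.parent_node._fair + length / node._n_tips
        if node.is_leaf():
            ed[node.taxon.label] = node._fair
    return pd.Series(ed, name="ED").sort_index()


def ge_from_category(category: str, ge_map: dict[str, float] | None = None) -> float:
    """100-year extinction probability for an IUCN threat category."""
    ge_map = ge_map if ge_map is not None else DEFAULT_GE_MAP
    if category not in ge_map:
        raise UnmappedCategoryError(
            f"category {category!r} not in GE map {sorted(ge_map)}"
        )
    return float(ge_map[category])


def edge_score(ed: float, ge: float) -> float:
    """EDGE = ln(1 + ED) + GE * ln 2."""
    if ed < 0:
        raise ValueError("ED must be >= 0")
    if not (0.0 <= ge <= 1.0):
        raise ValueError("GE must be in [0, 1]")
    return math.log1p(ed) + ge * math.log(2.0)


def species_scores(
    tree: dendropy.Tree,
    categories: dict[str, str],
    ge_map: dict[str, float] | None = None,
) -> pd.DataFrame:
    """ED, GE and EDGE for every tree tip.

    ``categories`` maps species id -> IUCN category; every tip must be
    covered.  Returns a DataFrame indexed by species with columns
    iucn_category, GE, ED, EDGE.
    """
    ed = evolutionary_distinctiveness(tree)
    missing = [s for s in ed.index if s not in categories]
    if missing:
        raise KeyError(f"no IUCN category for: {missing}")
    rows = []
    for sid, ed_val in ed.items():
        ge = ge_from_category(categories[sid], ge_map)
        rows.append(
            {
                "species": sid,
                "iucn_category": categories[sid],
                "GE": ge,
                "ED": float(ed_val),
                "EDGE": edge_score(float(ed_val), ge),
            }
        )
    return pd.DataFrame(rows).set_index("species")


_AGGREGATORS = {"max": np.max, "mean": np.mean, "sum": np.sum}


def map_edge(
    pam: PresenceAbsenceMatrix,
    scores: pd.DataFrame,
    aggregator: str = "max",
    column: str = "EDGE",
) -> DiversityGrid:
    """Rasterize per-species scores onto the coarse PAM cells.

    ``column`` selects the mapped quantity (EDGE by default; ED gives a
    map in My).  Cells aggregate the scores of their present species with
    the chosen function; the result rides in a DiversityGrid whose table
    gains an ``edge`` column.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    missing = [s for s in pam.species if s not in scores.index]
    if missing:
        raise UnmappedSpeciesError(f"no score for: {missing}")
    agg = _AGGREGATORS[aggregator]
    vals = scores.loc[pam.species, column].to_numpy(dtype=float)
    presence = pam.matrix.to_numpy(dtype=bool)
    out = np.full(len(presence), np.nan)
    for i in range(len(presence)):
        present = presence[i]
        if present.any():
            out[i] = agg(vals[present])
    table = pam.cells.copy()
    table["td"] = presence.sum(axis=1)
    table["edge"] = out
    return DiversityGrid(pam.scenario_id, pam.resolution_deg, table)
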