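import dendropy
import numpy as np
import pandas as pd
import pytest

import phylorange as pr


@pytest.fixture(scope="session")
def small_climate():
    """A 40x40 Andes-like climate stack (4 deg square at 6 arc-min)."""
    return pr.simulate_climate((-75.0, -2.0, -71.0, 2.0), 6.0, seed=7)


@pytest.fixture()
def toy_tree():
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


def records_frame(species, lons, lats, category="EN"):
    return pd.DataFrame(
        {
            "species": species,
            "lon": lons,
            "lat": lats,
            "iucn_category": category,
            "source": "synthetic",
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A cheap but complete end-to-end run (8 species, 40x40 grid)."""
    cfg = pr.PipelineConfig(n_species=8, extent=(-75.0, -2.0, -71.0, 2.0)).compact(2)
    return pr.run_study(cfg, seed=5)


def hand_pam_ranges():
    """Three species hand-placed on a 10x10 fine grid (1 deg square).

    Coarse 0.5-deg cells: (ci, cj) in {0,1} x {0,1}.  Expected PAM:
      cell (0,1): sp1, sp2, sp3   -> TD 3
      cell (1,0): sp2             -> TD 1
      cell (0,0): sp3             -> TD 1
      cell (1,1): sp3             -> TD 1
    """
    spec = pr.GridSpec(west=0.0, north=1.0, n_rows=10, n_cols=10, cellsize=0.1)

    def rng_map(sid, cells):
        presence = np.zeros(spec.shape, dtype=bool)
        for r, c in cells:
            presence[r, c] = True
        return pr.BinaryRangeMap(sid, "current", spec, presence, 0.5, True)

    ranges = [
        rng_map("sp1", [(0, 0), (1, 1)]),  # both fine cells in coarse (0,1)
        rng_map("sp2", [(0, 0), (9, 9)]),  # coarse (0,1) and (1,0)
        rng_map("sp3", [(0, 0), (0, 9), (9, 0)]),  # coarse (0,1),(1,1),(0,0)
    ]
    expected = {
        "0_1": {"sp1", "sp2", "sp3"},
        "1_0": {"sp2"},
        "0_0": {"sp3"},
        "1_1": {"sp3"},
    }
    return ranges, expected
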