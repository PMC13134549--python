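import dendropy
import numpy as np
import pandas as pd
import pytest

import phylorange as pr
from phylorange.diversity import (
    DegeneratePredictorError,
    DiversityGrid,
    EmptyComparisonError,
    ScenarioMismatchError,
    UnmappedSpeciesError,
    _loess_1d,
)

from conftest import hand_pam_ranges


def pd_oracle(tree, present):
    """Brute force: union of root-to-tip branch sets, then sum lengths."""
    edges = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in present:
            node = leaf
            while node.parent_node is not None:
                edges.add(node)
                node = node.parent_node
    return sum(n.edge.length or 0.0 for n in edges)


def grid_from(td, pdv=None):
    n = len(td)
    table = pd.DataFrame(
        {"lon": np.arange(n) * 0.5, "lat": np.zeros(n), "td": td},
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    if pdv is not None:
        table["pd"] = pdv
    return DiversityGrid("current", 0.5, table)


class TestStackPam:
    def test_hand_fixture_matches_enumeration(self):
        ranges, expected = hand_pam_ranges()
        pam = pr.stack_pam(ranges, 0.5)
        assert set(pam.matrix.index) == set(expected)
        for cell, species in expected.items():
            present = {s for s in pam.species if pam.matrix.loc[cell, s] == 1}
            assert present == species

    def test_single_fine_cell_single_presence(self):
        ranges, _ = hand_pam_ranges()
        pam = pr.stack_pam([ranges[0]], 0.5)
        assert pam.matrix.to_numpy().sum() == 1

    def test_two_fine_cells_same_coarse_cell_aggregate(self):
        ranges, _ = hand_pam_ranges()
        pam = pr.stack_pam([ranges[0]], 0.5)  # sp1 occupies 2 fine cells, 1 coarse
        assert pam.matrix["sp1"].sum() == 1

    def test_mixed_scenarios_rejected(self):
        ranges, _ = hand_pam_ranges()
        bad = pr.BinaryRangeMap("spX", "future", ranges[0].spec, ranges[0].presence, 0.5, True)
        with pytest.raises(ScenarioMismatchError):
            pr.stack_pam([ranges[0], bad])

    def test_coarse_td_at_least_fine_richness(self, small_study):
        # coarse-graining can only merge, never lose, species
        pam = small_study.pam_current
        ranges = list(small_study.current_ranges.values())
        fine_rich = np.zeros(ranges[0].spec.shape, dtype=int)
        for r in ranges:
            fine_rich += r.presence
        td = pr.taxonomic_diversity(pam).table["td"]
        assert td.max() >= fine_rich.max()


class TestTaxonomicDiversity:
    def test_hand_fixture_row_sums(self):
        ranges, expected = hand_pam_ranges()
        grid = pr.taxonomic_diversity(pr.stack_pam(ranges, 0.5))
        for cell, species in expected.items():
            assert grid.table.loc[cell, "td"] == len(species)

    def test_full_row_counts_all_species(self):
        ranges, _ = hand_pam_ranges()
        grid = pr.taxonomic_diversity(pr.stack_pam(ranges, 0.5))
        assert grid.table["td"].max() == 3


class TestFaithPD:
    def test_toy_tree_pair(self, toy_tree):
        ranges, _ = hand_pam_ranges()
        spec = ranges[0].spec
        pres = np.zeros(spec.shape, dtype=bool)
        pres[0, 0] = True
        empty = np.zeros(spec.shape, dtype=bool)
        maps = [
            pr.BinaryRangeMap(s, "current", spec, pres, 0.5, True) for s in ("A", "B")
        ] + [pr.BinaryRangeMap("C", "current", spec, empty, 0.5, True)]
        pam = pr.stack_pam(maps, 0.5)
        grid = pr.faith_pd(pam, toy_tree)
        assert grid.table["pd"].iloc[0] == pytest.approx(3.0)

    def test_toy_tree_full_assemblage_is_total_length(self, toy_tree):
        ranges, _ = hand_pam_ranges()
        spec = ranges[0].spec
        pres = np.zeros(spec.shape, dtype=bool)
        pres[0, 0] = True
        maps = [
            pr.BinaryRangeMap(s, "current", spec, pres, 0.5, True) for s in ("A", "B", "C")
        ]
        grid = pr.faith_pd(pr.stack_pam(maps, 0.5), toy_tree)
        assert grid.table["pd"].iloc[0] == pytest.approx(5.0)

    def test_single_species_rooted_vs_unrooted(self, toy_tree):
        ranges, _ = hand_pam_ranges()
        spec = ranges[0].spec
        pres = np.zeros(spec.shape, dtype=bool)
        pres[0, 0] = True
        pam = pr.stack_pam([pr.BinaryRangeMap("C", "current", spec, pres, 0.5, True)], 0.5)
        rooted = pr.faith_pd(pam, toy_tree, include_root=True)
        unrooted = pr.faith_pd(pam, toy_tree, include_root=False)
        assert rooted.table["pd"].iloc[0] == pytest.approx(2.0)  # root-to-tip of C
        assert unrooted.table["pd"].iloc[0] == 0.0

    def test_missing_species_listed(self, toy_tree):
        ranges, _ = hand_pam_ranges()
        pam = pr.stack_pam(ranges, 0.5)  # sp1..sp3 not in toy tree
        with pytest.raises(UnmappedSpeciesError):
            pr.faith_pd(pam, toy_tree)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 15))
        tree = pr.simulate_tree(n_tips, 30.0, seed=seed)
        labels = [t.label for t in tree.taxon_namespace]
        spec = pr.GridSpec(west=0, north=5, n_rows=10, n_cols=1, cellsize=0.5)
        maps = []
        for s in labels:
            pres = rng.random(spec.shape) < 0.4
            maps.append(pr.BinaryRangeMap(s, "current", spec, pres, 0.5, True))
        pam = pr.stack_pam(maps, 0.5)
        grid = pr.faith_pd(pam, tree)
        for cell_id in pam.matrix.index:
            present = {s for s in labels if pam.matrix.loc[cell_id, s] == 1}
            assert grid.table.loc[cell_id, "pd"] == pytest.approx(
                pd_oracle(tree, present), abs=1e-9
            )

    def test_pd_monotone_and_bounded(self, toy_tree):
        ranges, _ = hand_pam_ranges()
        spec = ranges[0].spec
        pres = np.zeros(spec.shape, dtype=bool)
        pres[0, 0] = True
        total = toy_tree.length()
        last = 0.0
        for subset in (["A"], ["A", "B"], ["A", "B", "C"]):
            maps = [pr.BinaryRangeMap(s, "current", spec, pres, 0.5, True) for s in subset]
            val = pr.faith_pd(pr.stack_pam(maps, 0.5), toy_tree).table["pd"].iloc[0]
            assert val >= last
            assert val <= total + 1e-12
            last = val
        assert last == pytest.approx(total)


class TestLoessResiduals:
    def test_exact_line_reproduced(self):
        rng = np.random.default_rng(0)
        td = rng.integers(1, 20, 60).astype(float)
        grid = grid_from(td, 2.0 * td + 1.0)
        out = pr.loess_residuals(grid)
        res = out.table["residual"].dropna()
        assert res.abs().max() < 1e-6 * (grid.table["pd"].max() - grid.table["pd"].min())

    def test_replication_invariance(self):
        rng = np.random.default_rng(1)
        td = rng.integers(1, 15, 40).astype(float)
        pdv = 2 * td + rng.normal(0, 1, 40)
        fit1 = _loess_1d(td, pdv, 0.75, 2)
        fit2 = _loess_1d(np.tile(td, 2), np.tile(pdv, 2), 0.75, 2)[:40]
        assert np.allclose(fit1, fit2, atol=1e-8)

    def test_heteroscedastic_noise_recovered(self):
        rng = np.random.default_rng(42)
        td = rng.integers(1, 25, 200).astype(float)
        noise = rng.normal(0, 0.3 * td)
        grid = grid_from(td, 2 * td + noise)
        out = pr.loess_residuals(grid)
        res = out.table["residual"].to_numpy()
        assert abs(res.mean()) < 0.05 * res.std()
        hi = np.abs(noise) > noise.std()
        agree = np.mean(np.sign(res[hi]) == np.sign(noise[hi]))
        assert agree >= 0.8

    def test_too_few_cells_rejected(self):
        grid = grid_from([1, 2, 3], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pr.loess_residuals(grid)

    def test_degenerate_predictor_rejected(self):
        grid = grid_from([2.0] * 12, list(range(12)))
        with pytest.raises(DegeneratePredictorError):
            pr.loess_residuals(grid)


class TestPDChange:
    def test_identity_future_zero_loss(self):
        g = grid_from([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])
        out = pr.pd_change(g, g)
        assert out.mean_loss_percent == pytest.approx(0.0)
        assert out.n_cells == 4

    def test_proportional_shrinkage(self):
        cur = grid_from([1, 2, 3], [10.0, 20.0, 30.0])
        fut = grid_from([1, 2, 3], [7.0, 14.0, 21.0])
        assert pr.pd_change(cur, fut).mean_loss_percent == pytest.approx(30.0)

    def test_missing_future_cells_are_complete_loss(self):
        cur = grid_from([1, 1], [10.0, 10.0])
        fut = DiversityGrid("f", 0.5, cur.table.iloc[:1].copy())
        out = pr.pd_change(cur, fut)
        assert out.per_cell["loss_percent"].tolist() == [0.0, 100.0]

    def test_no_baseline_rejected(self):
        g = grid_from([0, 0], [0.0, 0.0])
        with pytest.raises(EmptyComparisonError):
            pr.pd_change(g, g)
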