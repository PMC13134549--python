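import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylorange as pr
from phylorange.grids import GridSpec, haversine_km
from phylorange.sdm import (
    DegenerateLabelsError,
    ReplicateModel,
    SuitabilityMap,
    WrongPathError,
    evaluate_tss,
)

from conftest import records_frame


class FakePredictor:
    """Constant- or array-valued probability stub."""

    classes_ = np.array([0, 1])

    def __init__(self, values):
        self.values = values

    def predict_proba(self, X):
        p = np.broadcast_to(np.asarray(self.values, dtype=float), (len(X),)).copy()
        return np.column_stack([1 - p, p])


def fake_replicate(tss, value, variables=("temperature", "precipitation")):
    return ReplicateModel(
        algorithm="RF",
        replicate_id=0,
        predictor=FakePredictor(value),
        variables=tuple(variables),
        tss=tss,
        omission_rate=0.0,
        eval_threshold=0.5,
    )


# ---------------------------------------------------------------------------
# TSS evaluation
# ---------------------------------------------------------------------------

class TestEvaluateTSS:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        tss, omission, thr = evaluate_tss(scores, labels)
        assert tss == 1.0
        assert omission == 0.0
        assert thr == 0.8  # lowest threshold attaining the maximum

    def test_hand_confusion_matrix(self):
        # at the optimum threshold (0.8): TP=8, FN=2, TN=9, FP=1
        scores = np.concatenate([[0.8] * 8, [0.1] * 2, [0.2] * 9, [0.9]])
        labels = np.concatenate([np.ones(10), np.zeros(10)])
        tss, omission, thr = evaluate_tss(scores, labels)
        assert tss == pytest.approx(0.7)  # 0.8 + 0.9 - 1
        assert omission == pytest.approx(0.2)
        assert thr == 0.8

    def test_random_predictions_have_no_skill(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            scores = rng.random(500)
            labels = rng.integers(0, 2, 500)
            if labels.min() == labels.max():
                continue
            vals.append(evaluate_tss(scores, labels)[0])
        assert abs(np.mean(vals)) < 0.1

    def test_constant_predictions_zero_with_warning(self):
        with pytest.warns(UserWarning):
            tss, omission, thr = evaluate_tss([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert tss == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            evaluate_tss([0.1, 0.9], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_threshold_membership(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        scores = rng.random(n)
        labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
        tss, omission, thr = evaluate_tss(scores, labels)
        assert -1.0 <= tss <= 1.0
        assert 0.0 <= omission <= 1.0
        assert thr in scores


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------

class TestPseudoAbsences:
    @pytest.fixture()
    def area_and_records(self, small_climate):
        lon = small_climate.spec.lon_centers()[20]
        lat = small_climate.spec.lat_centers()[20]
        records = records_frame(["a"], [lon], [lat])
        area = pr.build_accessible_area(records, small_climate, buffer_km=300)
        return area, records

    def test_min_distance_enforced_brute_force(self, small_climate, area_and_records):
        area, records = area_and_records
        pa = pr.sample_pseudoabsences(
            area, records, small_climate, n=200, min_dist_km=4.5, seed=1
        )
        d = haversine_km(
            pa.points["lon"].to_numpy()[:, None],
            pa.points["lat"].to_numpy()[:, None],
            records["lon"].to_numpy()[None, :],
            records["lat"].to_numpy()[None, :],
        )
        assert d.min() >= 4.5

    def test_zero_distance_still_excludes_occurrence_cells(self, small_climate, area_and_records):
        area, records = area_and_records
        pa = pr.sample_pseudoabsences(
            area, records, small_climate, n=5000, min_dist_km=0.0, seed=1
        )
        assert (20, 20) not in set(zip(pa.rows, pa.cols))

    def test_capped_draw_returns_all_eligible(self, small_climate, area_and_records):
        area, records = area_and_records
        n_eligible = int(area.mask.sum()) - 1  # minus the occurrence cell
        with pytest.warns(UserWarning):
            pa = pr.sample_pseudoabsences(
                area, records, small_climate, n=10**6, min_dist_km=0.0, seed=1
            )
        assert len(pa.points) == n_eligible


# ---------------------------------------------------------------------------
# Replicates and ensemble
# ---------------------------------------------------------------------------

def _separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 2))
    y = (x[:, 0] > 0).astype(int)
    return x, y


class TestFitReplicates:
    def test_default_protocol_yields_thirty_models(self):
        x, y = _separable_data()
        models = pr.fit_replicates(x, y, ("v1", "v2"), n_reps=10, seed=0)
        assert len(models) == 30
        assert {m.algorithm for m in models} == {"BRT", "RF", "SVM"}

    def test_single_model_case(self):
        x, y = _separable_data()
        models = pr.fit_replicates(x, y, ("v1", "v2"), algorithms=("RF",), n_reps=1, seed=0)
        assert len(models) == 1

    def test_separable_data_high_skill(self):
        x, y = _separable_data(n=300, seed=1)
        models = pr.fit_replicates(x, y, ("v1", "v2"), n_reps=2, seed=1)
        assert all(m.tss >= 0.9 for m in models)

    def test_single_class_rejected(self):
        x, _ = _separable_data()
        with pytest.raises(DegenerateLabelsError):
            pr.fit_replicates(x, np.ones(len(x), dtype=int), ("v1", "v2"))


class TestEnsemble:
    def test_single_replicate_identity(self, small_climate):
        rep = fake_replicate(0.8, 0.37)
        out = pr.ensemble([rep], small_climate)
        assert np.allclose(out.values[np.isfinite(out.values)], 0.37)

    def test_equal_tss_is_plain_mean(self, small_climate):
        reps = [fake_replicate(0.5, 0.2), fake_replicate(0.5, 0.8)]
        out = pr.ensemble(reps, small_climate)
        assert np.allclose(out.values[np.isfinite(out.values)], 0.5)

    def test_tss_proportional_weights_hand_computed(self, small_climate):
        # tss 0.2/0.4/0.8 -> weights 1/7, 2/7, 4/7 on predictions 0.1/0.5/0.9
        reps = [
            fake_replicate(0.2, 0.1),
            fake_replicate(0.4, 0.5),
            fake_replicate(0.8, 0.9),
        ]
        out = pr.ensemble(reps, small_climate)
        expected = (1 * 0.1 + 2 * 0.5 + 4 * 0.9) / 7
        assert np.allclose(out.values[np.isfinite(out.values)], expected)

    def test_low_skill_models_excluded(self, small_climate):
        reps = [fake_replicate(0.0, 1.0), fake_replicate(0.5, 0.25)]
        out = pr.ensemble(reps, small_climate, tss_floor=0.0)
        assert np.allclose(out.values[np.isfinite(out.values)], 0.25)

    def test_no_usable_model_raises(self, small_climate):
        with pytest.raises(pr.sdm.NoUsableModelError):
            pr.ensemble([fake_replicate(-0.1, 0.5)], small_climate)

    def test_convex_combination_bounds(self, small_climate):
        rng = np.random.default_rng(0)
        n = int(small_climate.valid_mask().sum())
        vals = [rng.random(n) for _ in range(3)]
        reps = [fake_replicate(t, v) for t, v in zip((0.3, 0.6, 0.9), vals)]
        out = pr.ensemble(reps, small_climate)
        flat = out.values[np.isfinite(out.values)]
        lo = np.minimum.reduce(vals)
        hi = np.maximum.reduce(vals)
        assert np.all(flat >= lo - 1e-12)
        assert np.all(flat <= hi + 1e-12)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def _suit_map_1d(values):
    spec = GridSpec(west=0.0, north=0.1, n_rows=1, n_cols=len(values), cellsize=0.1)
    return SuitabilityMap("sp", "current", spec, np.asarray(values, dtype=float)[None, :])


def _records_at_all_cells(suit):
    lons = suit.spec.lon_centers()
    lats = np.full(len(lons), suit.spec.lat_centers()[0])
    return records_frame(["sp"] * len(lons), lons, lats)


class TestBinarize:
    def test_ninety_percent_retention_order_statistic(self):
        suit = _suit_map_1d([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        records = _records_at_all_cells(suit)
        out = pr.binarize(suit, records, retention=0.9)
        assert out.threshold_used == pytest.approx(0.2)
        assert out.n_cells == 9

    def test_full_retention_keeps_every_occurrence(self):
        suit = _suit_map_1d([0.9, 0.3, 0.6])
        records = _records_at_all_cells(suit)
        out = pr.binarize(suit, records, retention=1.0)
        assert out.threshold_used == pytest.approx(0.3)
        assert out.presence.all()

    def test_uniform_suitability_fills_grid(self):
        suit = _suit_map_1d([0.5] * 8)
        records = _records_at_all_cells(suit)
        out = pr.binarize(suit, records, retention=0.9)
        assert out.presence.all()

    def test_retention_monotonicity(self):
        rng = np.random.default_rng(3)
        suit = _suit_map_1d(rng.random(30))
        records = _records_at_all_cells(suit)
        low = pr.binarize(suit, records, retention=0.7)
        high = pr.binarize(suit, records, retention=0.9)
        assert high.threshold_used <= low.threshold_used
        assert np.all(high.presence[low.presence])

    def test_zero_suitability_everywhere_warns_empty(self):
        suit = _suit_map_1d([0.0, 0.0, 0.0])
        records = _records_at_all_cells(suit)
        with pytest.warns(UserWarning):
            out = pr.binarize(suit, records)
        assert out.n_cells == 0


# ---------------------------------------------------------------------------
# Projection and the unmodeled path
# ---------------------------------------------------------------------------

class TestProjection:
    def test_identity_transfer_is_exact(self, small_study):
        sid = small_study.modeled_species[0]
        result = small_study.sdm_results[sid]
        fx = small_study.fixture
        suit, binary = pr.project(
            result.replicates, fx.climate_current, threshold=result.threshold, species_id=sid
        )
        a, b = suit.values, result.suitability_current.values
        assert np.array_equal(np.nan_to_num(a, nan=-1), np.nan_to_num(b, nan=-1))
        assert np.array_equal(binary.presence, result.range_current.presence)

    def test_extreme_warming_empties_every_range(self, small_study):
        from phylorange.synthetic import ScenarioDelta

        fx = small_study.fixture
        hot = pr.apply_scenario(fx.climate_current, ScenarioDelta("hot", 20.0, 0.0))
        for sid in small_study.modeled_species:
            result = small_study.sdm_results[sid]
            _, binary = pr.project(
                result.replicates, hot, threshold=result.threshold, species_id=sid
            )
            assert binary.n_cells == 0

    def test_warming_shifts_presence_upslope(self, small_study):
        from phylorange.synthetic import ScenarioDelta

        fx = small_study.fixture
        elev = fx.climate_current.layers["elevation"]
        warm = pr.apply_scenario(fx.climate_current, ScenarioDelta("w", 2.0, 0.0))
        moved_up = 0
        compared = 0
        for sid in small_study.modeled_species:
            result = small_study.sdm_results[sid]
            _, fut = pr.project(
                result.replicates, warm, threshold=result.threshold, species_id=sid
            )
            cur = result.range_current.presence
            if fut.n_cells == 0 or cur.sum() == 0:
                continue
            compared += 1
            if elev[fut.presence].mean() > elev[cur].mean():
                moved_up += 1
        assert compared >= 3
        assert moved_up / compared >= 0.8


class TestRasterizeUnmodeled:
    def test_records_become_pixels(self, small_climate):
        lons = small_climate.spec.lon_centers()[[3, 8, 13]]
        lats = small_climate.spec.lat_centers()[[3, 8, 13]]
        records = records_frame(["u"] * 3, lons, lats)
        out = pr.rasterize_unmodeled(records, small_climate)
        assert out.n_cells == 3
        assert not out.modeled_flag

    def test_shared_cells_deduplicate(self, small_climate):
        lon = small_climate.spec.lon_centers()[3]
        lat = small_climate.spec.lat_centers()[3]
        lon2 = small_climate.spec.lon_centers()[8]
        records = records_frame(["u"] * 4, [lon, lon, lon2, lon2], [lat] * 4)
        out = pr.rasterize_unmodeled(records, small_climate)
        assert out.n_cells == 2

    def test_modelable_species_rejected(self, small_climate):
        lons = small_climate.spec.lon_centers()[:5]
        lats = small_climate.spec.lat_centers()[:5]
        records = records_frame(["u"] * 5, lons, lats)
        with pytest.raises(WrongPathError):
            pr.rasterize_unmodeled(records, small_climate)
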