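"""Ensemble species distribution modeling.

Per species: presences (occurrence cells) and random pseudo-absences drawn
inside the accessible area M are used to fit replicated classifiers
(boosted regression trees, random forests, support-vector machines) on
70/30 stratified subsampling splits.  Each replicate is scored on its
held-out 30% with the True Skill Statistic (TSS = sensitivity +
specificity - 1, maximised over observed prediction values) and the
omission rate.  Replicates with positive TSS are averaged cell-wise with
TSS-proportional weights; the ensemble is binarized at the suitability
threshold that retains a fixed fraction (default 90%) of occurrence cells,
and the same weights and threshold are reused when transferring the
ensemble onto future climate scenarios.  Species with fewer than five
records are not modeled: their occurrence cells become the (current-only)
range directly.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grids import ClimateGrid, GridSpec, haversine_km, require_aligned
from .occurrences import AccessibleArea, occurrence_cells

__all__ = [
    "PseudoAbsenceSet",
    "ReplicateModel",
    "SuitabilityMap",
    "BinaryRangeMap",
    "DegenerateLabelsError",
    "NoUsableModelError",
    "WrongPathError",
    "sample_pseudoabsences",
    "evaluate_tss",
    "fit_replicates",
    "ensemble",
    "binarize",
    "project",
    "rasterize_unmodeled",
    "fit_species_sdm",
    "SpeciesSDMResult",
]


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


class NoUsableModelError(RuntimeError):
    """No replicate exceeds the TSS floor."""


class WrongPathError(ValueError):
    """A species was routed to the wrong modeling path."""


@dataclasses.dataclass
class PseudoAbsenceSet:
    species_id: str
    points: pd.DataFrame  # columns lon, lat
    rows: np.ndarray
    cols: np.ndarray
    n_target: int
    min_dist_km: float


@dataclasses.dataclass
class ReplicateModel:
    algorithm: str
    replicate_id: int
    predictor: object
    variables: tuple[str, ...]
    tss: float
    omission_rate: float
    eval_threshold: float
    #: per-variable (min, max) of the training presences; predictions are
    #: truncated outside the occupied climate envelope (niche conservatism,
    #: no extrapolation into non-analog climates)
    feature_range: tuple[np.ndarray, np.ndarray] | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Probability of presence for each feature row."""
        proba = self.predictor.predict_proba(features)
        classes = list(self.predictor.classes_)
        return proba[:, classes.index(1)]


@dataclasses.dataclass
class SuitabilityMap:
    species_id: str
    scenario_id: str
    spec: GridSpec
    values: np.ndarray  # float in [0,1], NaN off-grid

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclasses.dataclass
class BinaryRangeMap:
    species_id: str
    scenario_id: str
    spec: GridSpec
    presence: np.ndarray  # bool
    threshold_used: float | None
    modeled_flag: bool

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)
        if self.modeled_flag and self.threshold_used is None:
            raise ValueError("modeled range maps must record the threshold used")

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------

def sample_pseudoabsences(
    area: AccessibleArea,
    occurrences: pd.DataFrame,
    climate: ClimateGrid,
    n: int = 1000,
    min_dist_km: float = 4.5,
    seed: int = 0,
) -> PseudoAbsenceSet:
    """Uniform random background cells inside M, away from presences.

    Eligible cells lie inside the accessible area, carry valid climate, are
    not occurrence cells, and sit at least ``min_dist_km`` (great-circle,
    between cell centers) from every occurrence cell.  If fewer than ``n``
    cells are eligible all of them are returned with a warning.
    """
    require_aligned(area.spec, climate.spec)
    spec = area.spec
    occ = occurrence_cells(occurrences, spec)
    eligible = area.mask & climate.valid_mask()
    if len(occ):
        eligible[occ[:, 0], occ[:, 1]] = False
        lon_c, lat_c = spec.center_mesh()
        lons = spec.lon_centers()[occ[:, 1]]
        lats = spec.lat_centers()[occ[:, 0]]
        if min_dist_km > 0:
            too_close = np.zeros(spec.shape, dtype=bool)
            for olon, olat in zip(lons, lats):
                too_close |= haversine_km(lon_c, lat_c, olon, olat) < min_dist_km
            eligible &= ~too_close
    rows, cols = np.nonzero(eligible)
    if len(rows) == 0:
        warnings.warn(f"{area.species_id}: exclusion zone covers the whole accessible area")
        empty = pd.DataFrame(columns=["lon", "lat"])
        return PseudoAbsenceSet(area.species_id, empty, rows, cols, n, min_dist_km)
    rng = np.random.default_rng(seed)
    if len(rows) <= n:
        if len(rows) < n:
            warnings.warn(
                f"{area.species_id}: only {len(rows)} eligible cells for {n} pseudo-absences"
            )
        take = np.arange(len(rows))
    else:
        take = rng.choice(len(rows), size=n, replace=False)
    r, c = rows[take], cols[take]
    points = pd.DataFrame({"lon": spec.lon_centers()[c], "lat": spec.lat_centers()[r]})
    return PseudoAbsenceSet(area.species_id, points, r, c, n, min_dist_km)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_tss(scores, labels) -> tuple[float, float, float]:
    """Maximise TSS over the observed prediction values.

    Returns ``(tss, omission_rate, eval_threshold)`` where the threshold is
    the lowest value attaining the maximum of sensitivity + specificity - 1
    (prediction rule: score >= threshold means presence) and the omission
    rate is the false-negative fraction at that threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise DegenerateLabelsError("labels contain a single class")
    ts = np.unique(scores)
    if len(ts) == 1:
        warnings.warn("constant predictions: TSS reported as 0")
        return 0.0, 0.0, float(ts[0])
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]
    pos_total = int(y.sum())
    neg_total = len(y) - pos_total
    cum_pos = np.concatenate([[0], np.cumsum(y)])
    idx = np.searchsorted(s, ts, side="left")
    tp = pos_total - cum_pos[idx]
    fp = neg_total - (idx - cum_pos[idx])
    sens = tp / pos_total
    spec = 1.0 - fp / neg_total
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # ts ascending -> first max = lowest threshold
    return float(tss[best]), float(1.0 - sens[best]), float(ts[best])


# ---------------------------------------------------------------------------
# Replicated model fitting
# ---------------------------------------------------------------------------

def _make_estimator(algorithm: str, seed: int):
    # Shallow, slow-learning members with balanced class weights: presence
    # points are heavily outnumbered by the 1,000 pseudo-absences, and the
    # climate response being modeled is smooth, so strong regularization
    # keeps the ensemble from memorizing individual record clusters.
    if algorithm == "BRT":
        return GradientBoostingClassifier(
            n_estimators=150, learning_rate=0.03, max_depth=2, subsample=0.7, random_state=seed
        )
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=200,
            min_samples_leaf=25,
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "SVM":
        return make_pipeline(
            StandardScaler(),
            SVC(C=0.5, gamma="scale", class_weight="balanced", probability=True, random_state=seed),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fit_replicates(
    features: np.ndarray,
    labels: np.ndarray,
    variables: tuple[str, ...],
    algorithms: tuple[str, ...] = ("BRT", "RF", "SVM"),
    n_reps: int = 10,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> list[ReplicateModel]:
    """Fit ``len(algorithms) x n_reps`` models on stratified 70/30 subsamples.

    Every replicate draws an independent split; evaluation (TSS, omission)
    uses only its held-out 30%.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise DegenerateLabelsError("both classes are required to fit replicates")
    models: list[ReplicateModel] = []
    for rep in range(n_reps):
        split_seed = (seed + 7919 * rep) % (2**31 - 1)
        x_tr, x_te, y_tr, y_te = train_test_split(
            features,
            labels,
            test_size=test_fraction,
            stratify=labels,
            random_state=split_seed,
        )
        for k, algo in enumerate(algorithms):
            est = _make_estimator(algo, (split_seed + k) % (2**31 - 1))
            est.fit(x_tr, y_tr)
            proba = est.predict_proba(x_te)
            scores = proba[:, list(est.classes_).index(1)]
            tss, omission, thr = evaluate_tss(scores, y_te)
            models.append(
                ReplicateModel(
                    algorithm=algo,
                    replicate_id=rep,
                    predictor=est,
                    variables=tuple(variables),
                    tss=tss,
                    omission_rate=omission,
                    eval_threshold=thr,
                    feature_range=(x_tr[y_tr == 1].min(axis=0), x_tr[y_tr == 1].max(axis=0)),
                )
            )
    return models


def evaluation_table(replicates: list[ReplicateModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "algorithm": [m.algorithm for m in replicates],
            "replicate": [m.replicate_id for m in replicates],
            "tss": [m.tss for m in replicates],
            "omission_rate": [m.omission_rate for m in replicates],
            "eval_threshold": [m.eval_threshold for m in replicates],
        }
    )


# ---------------------------------------------------------------------------
# Ensemble, binarization, projection
# ---------------------------------------------------------------------------

def ensemble(
    replicates: list[ReplicateModel],
    climate: ClimateGrid,
    tss_floor: float = 0.0,
    species_id: str = "",
) -> SuitabilityMap:
    """TSS-weighted cell-wise mean of replicate predictions.

    Replicates with TSS <= ``tss_floor`` are excluded; remaining weights
    are TSS-proportional and sum to one, so the output is a convex
    combination of the member predictions.
    """
    usable = [m for m in replicates if m.tss > tss_floor]
    if not usable:
        raise NoUsableModelError(f"no replicate with TSS above {tss_floor}")
    variables = usable[0].variables
    for m in usable:
        if m.variables != variables:
            raise ValueError("replicates trained on different variable sets")
    missing = [v for v in variables if v not in climate.layers]
    if missing:
        raise KeyError(f"climate grid lacks variables {missing}")
    valid = climate.valid_mask()
    rows, cols = np.nonzero(valid)
    feats = climate.values_at(rows, cols, variables)
    weights = np.array([m.tss for m in usable], dtype=float)
    weights /= weights.sum()
    agg = np.zeros(len(rows))
    for w, m in zip(weights, usable):
        agg += w * m.predict(feats)
    # no-extrapolation rule: climates outside the union of the members'
    # training envelopes are non-analog and scored unsuitable
    ranges = [m.feature_range for m in usable if m.feature_range is not None]
    if ranges:
        lo = np.min([r[0] for r in ranges], axis=0)
        hi = np.max([r[1] for r in ranges], axis=0)
        novel = np.any((feats < lo) | (feats > hi), axis=1)
        agg[novel] = 0.0
    values = np.full(climate.spec.shape, np.nan)
    values[rows, cols] = np.clip(agg, 0.0, 1.0)
    return SuitabilityMap(species_id, climate.scenario_id, climate.spec, values)


def binarize(
    suit: SuitabilityMap,
    occurrences: pd.DataFrame,
    retention: float = 0.9,
) -> BinaryRangeMap:
    """Threshold the ensemble at the occurrence-retention quantile.

    The threshold t is the largest suitability value such that at least
    ``retention`` of the species' occurrence cells have suitability >= t,
    i.e. the (1 - retention) lower quantile (as an order statistic) of the
    ensemble suitability sampled at occurrence cells.  Presence = cells
    with suitability >= t.
    """
    if not (0.0 < retention <= 1.0):
        raise ValueError("retention must be in (0, 1]")
    cells = occurrence_cells(occurrences, suit.spec)
    if len(cells) == 0:
        raise ValueError("species has no occurrence cell on the grid")
    s = suit.values[cells[:, 0], cells[:, 1]]
    s = s[np.isfinite(s)]
    if s.size == 0 or s.max() <= 0:
        warnings.warn(f"{suit.species_id}: zero suitability at every occurrence; empty range")
        return BinaryRangeMap(
            suit.species_id,
            suit.scenario_id,
            suit.spec,
            np.zeros(suit.spec.shape, dtype=bool),
            threshold_used=float("inf"),
            modeled_flag=True,
        )
    s_desc = np.sort(s)[::-1]
    k = int(np.ceil(retention * len(s_desc)))
    t = float(s_desc[k - 1])
    presence = np.where(np.isfinite(suit.values), (suit.values >= t) & (suit.values > 0), False)
    return BinaryRangeMap(suit.species_id, suit.scenario_id, suit.spec, presence, t, True)


def project(
    replicates: list[ReplicateModel],
    future: ClimateGrid,
    threshold: float,
    tss_floor: float = 0.0,
    species_id: str = "",
) -> tuple[SuitabilityMap, BinaryRangeMap]:
    """Transfer the ensemble onto a future climate.

    Uses the same TSS weights and the training-time binarization threshold;
    projecting onto the training climate therefore reproduces the current
    ensemble exactly.
    """
    suit = ensemble(replicates, future, tss_floor=tss_floor, species_id=species_id)
    presence = np.where(np.isfinite(suit.values), (suit.values >= threshold) & (suit.values > 0), False)
    binary = BinaryRangeMap(species_id, future.scenario_id, future.spec, presence, threshold, True)
    return suit, binary


def rasterize_unmodeled(
    occurrences: pd.DataFrame,
    grid: ClimateGrid,
    max_records: int = 4,
) -> BinaryRangeMap:
    """Current-only range for species with too few records to model.

    Presence is exactly the occupied cells; such species never enter
    future-scenario products.
    """
    sids = occurrences["species"].unique()
    if len(sids) != 1:
        raise ValueError("rasterize_unmodeled expects records of a single species")
    if len(occurrences) > max_records:
        raise WrongPathError(
            f"{sids[0]}: {len(occurrences)} records; species should be modeled instead"
        )
    if occurrences.empty:
        raise ValueError("species has no records")
    cells = occurrence_cells(occurrences, grid.spec)
    presence = np.zeros(grid.spec.shape, dtype=bool)
    presence[cells[:, 0], cells[:, 1]] = True
    return BinaryRangeMap(str(sids[0]), "current", grid.spec, presence, None, False)


# ---------------------------------------------------------------------------
# Per-species driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpeciesSDMResult:
    species_id: str
    replicates: list[ReplicateModel]
    evaluation: pd.DataFrame
    suitability_current: SuitabilityMap
    range_current: BinaryRangeMap
    threshold: float


def fit_species_sdm(
    species_records: pd.DataFrame,
    area: AccessibleArea,
    climate: ClimateGrid,
    variables: tuple[str, ...] = ("temperature", "precipitation"),
    n_pseudoabsences: int = 1000,
    min_dist_km: float = 4.5,
    algorithms: tuple[str, ...] = ("BRT", "RF", "SVM"),
    n_reps: int = 10,
    test_fraction: float = 0.3,
    tss_floor: float = 0.0,
    retention: float = 0.9,
    seed: int = 0,
) -> SpeciesSDMResult:
    """Fit the full per-species ensemble on the current climate."""
    spec = climate.spec
    occ = occurrence_cells(species_records, spec)
    if len(occ) < 1:
        raise ValueError("no on-grid occurrence cells")
    pa = sample_pseudoabsences(
        area, species_records, climate, n=n_pseudoabsences, min_dist_km=min_dist_km, seed=seed
    )
    if pa.points.empty:
        raise NoUsableModelError("no pseudo-absence cells available")
    pres_feats = climate.values_at(occ[:, 0], occ[:, 1], variables)
    abs_feats = climate.values_at(pa.rows, pa.cols, variables)
    features = np.vstack([pres_feats, abs_feats])
    labels = np.concatenate([np.ones(len(pres_feats), dtype=int), np.zeros(len(abs_feats), dtype=int)])
    keep = np.all(np.isfinite(features), axis=1)
    features, labels = features[keep], labels[keep]
    replicates = fit_replicates(
        features,
        labels,
        variables,
        algorithms=algorithms,
        n_reps=n_reps,
        test_fraction=test_fraction,
        seed=seed,
    )
    # the truncation envelope is a species-level property: use the full
    # presence set, not each replicate's 70% subsample, so no occurrence
    # cell is ever scored as non-analog climate
    pres_ok = pres_feats[np.all(np.isfinite(pres_feats), axis=1)]
    envelope = (pres_ok.min(axis=0), pres_ok.max(axis=0))
    for m in replicates:
        m.feature_range = envelope
    sid = str(species_records["species"].iloc[0])
    suit = ensemble(replicates, climate, tss_floor=tss_floor, species_id=sid)
    binary = binarize(suit, species_records, retention=retention)
    return SpeciesSDMResult(
        species_id=sid,
        replicates=replicates,
        evaluation=evaluation_table(replicates),
        suitability_current=suit,
        range_current=binary,
        threshold=float(binary.threshold_used),
    )
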