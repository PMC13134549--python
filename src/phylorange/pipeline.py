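"""End-to-end driver: synthetic study -> SDMs -> diversity -> prioritization.

One call runs the whole analysis on a seeded synthetic study: generate
climates/species/tree/protected areas, validate records, split species
into the modeled (>= 5 records) and unmodeled paths, fit the TSS-weighted
ensemble per modeled species and transfer it onto every future scenario,
stack presence-absence matrices, compute TD/PD/LOESS-residual grids and
per-scenario PD loss, score ED/GE/EDGE, and build the conservation
accounting table (areas, contractions, complete losses, protected
overlap).  Truth-recovery diagnostics (Jaccard overlap between modeled
and true ranges) come for free because the virtual species' niches are
known.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import conservation as cons
from . import diversity as dv
from . import edge as edge_mod
from . import sdm
from .config import PipelineConfig, species_seed
from .occurrences import build_accessible_area, validate_records
from .synthetic import StudyFixture, make_study_fixture

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_study"]


@dataclasses.dataclass
class StudyResult:
    fixture: StudyFixture
    validation: object
    sdm_results: dict[str, sdm.SpeciesSDMResult]
    current_ranges: dict[str, sdm.BinaryRangeMap]  # modeled + unmodeled
    future_ranges: dict[str, dict[str, sdm.BinaryRangeMap]]  # scenario -> species
    pam_current: dv.PresenceAbsenceMatrix
    pam_futures: dict[str, dv.PresenceAbsenceMatrix]
    diversity_current: dv.DiversityGrid
    diversity_futures: dict[str, dv.DiversityGrid]
    pd_changes: dict[str, dv.PDChangeSummary]
    scores: pd.DataFrame
    edge_grid: dv.DiversityGrid
    conservation_table: pd.DataFrame
    loss: cons.LossClassification
    jaccard: pd.Series  # per modeled species, current range vs truth

    @property
    def modeled_species(self) -> list[str]:
        return sorted(self.sdm_results)

    def summary(self) -> dict:
        """Headline numbers of the run (plain floats, JSON-friendly)."""
        ev = pd.concat([r.evaluation for r in self.sdm_results.values()])
        total_current = sum(
            cons.range_area_km2(r) for r in self.current_ranges.values()
        )
        out = {
            "n_species": len(self.fixture.species_ids),
            "n_modeled": len(self.sdm_results),
            "percent_modeled": 100.0 * len(self.sdm_results) / len(self.fixture.species_ids),
            "mean_tss": float(ev["tss"].mean()),
            "mean_omission_rate": float(ev["omission_rate"].mean()),
            "mean_truth_jaccard": float(self.jaccard.mean()),
            "total_current_area_km2": float(total_current),
            "n_complete_loss_any_scenario": self.loss.n_any,
            "n_complete_loss_all_scenarios": self.loss.n_all,
        }
        for scen, change in self.pd_changes.items():
            out[f"pd_loss_percent[{scen}]"] = change.mean_loss_percent
        tbl = self.conservation_table
        for scen in self.future_ranges:
            sub = tbl[tbl["scenario"] == scen]
            out[f"mean_contraction_percent[{scen}]"] = float(sub["contraction_percent"].mean())
            tot = float(sub["future_area_km2"].sum())
            inside = float(
                (sub["future_area_km2"] * sub["protected_percent"].fillna(0.0) / 100.0).sum()
            )
            out[f"total_future_area_km2[{scen}]"] = tot
            out[f"protected_percent[{scen}]"] = 100.0 * inside / tot if tot > 0 else float("nan")
        return out


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(a, b).sum() / union)


def run_study(config: PipelineConfig | None = None, seed: int = 0) -> StudyResult:
    """Run the full analysis on a synthetic study fixture."""
    cfg = config or PipelineConfig()
    fixture = make_study_fixture(cfg, seed)
    climate = fixture.climate_current
    validation = validate_records(fixture.occurrences, climate)
    records = validation.records

    sdm_results: dict[str, sdm.SpeciesSDMResult] = {}
    current_ranges: dict[str, sdm.BinaryRangeMap] = {}
    future_ranges: dict[str, dict[str, sdm.BinaryRangeMap]] = {
        scen: {} for scen in fixture.climate_futures
    }
    jaccard: dict[str, float] = {}

    for sid in fixture.species_ids:
        sp_records = records[records["species"] == sid]
        if sp_records.empty:
            logger.warning("%s: no valid records; species skipped", sid)
            continue
        if len(sp_records) < cfg.min_records_to_model:
            current_ranges[sid] = sdm.rasterize_unmodeled(
                sp_records, climate, max_records=cfg.min_records_to_model - 1
            )
            continue
        area = build_accessible_area(sp_records, climate, buffer_km=cfg.buffer_km)
        result = sdm.fit_species_sdm(
            sp_records,
            area,
            climate,
            variables=cfg.sdm_variables,
            n_pseudoabsences=cfg.n_pseudoabsences,
            min_dist_km=cfg.min_pseudoabsence_km,
            algorithms=cfg.algorithms,
            n_reps=cfg.n_replicates,
            test_fraction=cfg.test_fraction,
            tss_floor=cfg.tss_floor,
            retention=cfg.occurrence_retention,
            seed=species_seed(seed, sid),
        )
        sdm_results[sid] = result
        current_ranges[sid] = result.range_current
        jaccard[sid] = _jaccard(result.range_current.presence, fixture.truth_range(sid))
        for scen, future_climate in fixture.climate_futures.items():
            _, fut_range = sdm.project(
                result.replicates,
                future_climate,
                threshold=result.threshold,
                tss_floor=cfg.tss_floor,
                species_id=sid,
            )
            future_ranges[scen][sid] = fut_range

    pam_current = dv.stack_pam(list(current_ranges.values()), cfg.coarse_resolution_deg)
    pam_futures = {
        scen: dv.stack_pam(list(ranges.values()), cfg.coarse_resolution_deg)
        for scen, ranges in future_ranges.items()
        if ranges
    }

    div_current = dv.faith_pd(pam_current, fixture.tree, include_root=cfg.pd_include_root)
    div_current = dv.loess_residuals(div_current, span=cfg.loess_span, degree=cfg.loess_degree)
    div_futures = {
        scen: dv.faith_pd(pam, fixture.tree, include_root=cfg.pd_include_root)
        for scen, pam in pam_futures.items()
    }
    pd_changes = {scen: dv.pd_change(div_current, grid) for scen, grid in div_futures.items()}

    scores = edge_mod.species_scores(fixture.tree, fixture.categories, cfg.ge_map)
    edge_grid = edge_mod.map_edge(pam_current, scores, aggregator=cfg.edge_aggregator)

    modeled_current = {sid: current_ranges[sid] for sid in sdm_results}
    table = cons.build_conservation_table(modeled_current, future_ranges, fixture.protected)
    loss = cons.classify_loss(table)

    return StudyResult(
        fixture=fixture,
        validation=validation,
        sdm_results=sdm_results,
        current_ranges=current_ranges,
        future_ranges=future_ranges,
        pam_current=pam_current,
        pam_futures=pam_futures,
        diversity_current=div_current,
        diversity_futures=div_futures,
        pd_changes=pd_changes,
        scores=scores,
        edge_grid=edge_grid,
        conservation_table=table,
        loss=loss,
        jaccard=pd.Series(jaccard, dtype=float),
    )
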