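"""Pipeline configuration.

Every tunable knob of the analysis lives here so a run is fully described
by one :class:`PipelineConfig` plus one integer seed.  Defaults encode the
study conditions: a 10-degree square Andes-like domain gridded at 0.1
degree (100 x 100 cells), 40 virtual species, a 37-My ultrametric
phylogeny, four future climate scenarios (two GCM analogues x two SSP
analogues), and the ensemble protocol (1,000 pseudo-absences at >= 4.5 km
from presences, 70/30 subsampling replicates of boosted trees, random
forests and SVMs, TSS-weighted averaging, 90% occurrence-retention
binarization).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

#: 100-year extinction probabilities per IUCN threat category (editable;
#: the classic probability scheme behind EDGE scoring).
DEFAULT_GE_MAP: dict[str, float] = {"CR": 0.999, "EN": 0.667, "VU": 0.1}

#: Future-scenario deltas (scenario_id -> (temperature degC, precipitation mm)).
#: One warmer/drier GCM analogue and one milder/wetter one, each under an
#: intermediate and a high-emissions pathway.
DEFAULT_SCENARIOS: dict[str, tuple[float, float]] = {
    "gcmWarmDry_ssp245": (3.0, -120.0),
    "gcmWarmDry_ssp370": (4.5, -200.0),
    "gcmMildWet_ssp245": (2.5, 150.0),
    "gcmMildWet_ssp370": (3.4, 80.0),
}


@dataclasses.dataclass
class PipelineConfig:
    # --- synthetic domain -------------------------------------------------
    extent: tuple[float, float, float, float] = (-79.0, -5.0, -69.0, 5.0)
    resolution_arcmin: float = 6.0
    n_species: int = 40
    root_age_my: float = 37.0
    fraction_sparse_species: float = 0.15  # species given < 5 records
    records_min: int = 5
    records_max: int = 60
    occurrence_clustering: float = 0.25  # 0 = iid, 1 = tightly clustered
    category_weights: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CR": 11 / 69, "EN": 39 / 69, "VU": 19 / 69}
    )
    scenarios: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS)
    )
    protected_target_fraction: float = 0.35

    # --- occurrence processing -------------------------------------------
    buffer_km: float = 500.0

    # --- SDM ensemble ----------------------------------------------------
    sdm_variables: tuple[str, ...] = ("temperature", "precipitation")
    n_pseudoabsences: int = 1000
    min_pseudoabsence_km: float = 4.5
    algorithms: tuple[str, ...] = ("BRT", "RF", "SVM")
    n_replicates: int = 10
    test_fraction: float = 0.3
    tss_floor: float = 0.0
    occurrence_retention: float = 0.9
    min_records_to_model: int = 5

    # --- diversity / prioritization --------------------------------------
    coarse_resolution_deg: float = 0.5
    loess_span: float = 0.75
    loess_degree: int = 2
    pd_include_root: bool = True
    edge_aggregator: str = "max"
    ge_map: dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_GE_MAP))

    def compact(self, n_replicates: int = 2) -> "PipelineConfig":
        """A reduced-replication profile (same conditions, fewer model fits)."""
        return dataclasses.replace(self, n_replicates=n_replicates)

    # --- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["sdm_variables"] = list(self.sdm_variables)
        d["algorithms"] = list(self.algorithms)
        d["scenarios"] = {k: list(v) for k, v in self.scenarios.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "extent" in d:
            d["extent"] = tuple(d["extent"])
        for key in ("sdm_variables", "algorithms"):
            if key in d:
                d[key] = tuple(d[key])
        if "scenarios" in d:
            d["scenarios"] = {k: tuple(v) for k, v in d["scenarios"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def species_seed(global_seed: int, species_id: str) -> int:
    """Stable per-species seed derived from (global seed, species id).

    Uses CRC32 so every species is independently reproducible regardless of
    processing order; result is kept below 2**31.
    """
    import zlib

    h = zlib.crc32(f"{global_seed}:{species_id}".encode())
    return int(h % (2**31 - 1))
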