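"""Bundled reference datasets for threatened Neotropical glassfrogs.

Small published summary tables shipped with the package so the
accounting operations can be exercised on real numbers without any
download: the per-species range-contraction matrix (percent, per GCM x
SSP scenario) with EDGE scores, the occurrence-record and species census
by IUCN threat category, and the per-GCM mean phylogenetic-diversity loss
projections.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

#: Scenario column labels of the bundled contraction table.
SCENARIOS = (
    "CMCC-ESM2_SSP2-4.5",
    "GISS-E2-1-G_SSP2-4.5",
    "CMCC-ESM2_SSP3-7.0",
    "GISS-E2-1-G_SSP3-7.0",
)


def _data_path(name: str):
    return resources.files("phylorange.data").joinpath(name)


def load_contraction_table() -> pd.DataFrame:
    """Wide per-species table: four contraction columns (%) plus EDGE.

    100 marks complete loss of climatic suitability; negative values are
    expansions.  EDGE is NaN for species without genetic data.
    """
    with resources.as_file(_data_path("contraction_edge.csv")) as path:
        return pd.read_csv(path, index_col="species")


def load_contraction_long() -> pd.DataFrame:
    """Tidy version: species, genus, scenario, contraction_percent."""
    wide = load_contraction_table()
    long = (
        wide[list(SCENARIOS)]
        .reset_index()
        .melt(id_vars="species", var_name="scenario", value_name="contraction_percent")
    )
    long["genus"] = long["species"].str.split().str[0]
    return long


def load_census() -> dict:
    """Occurrence-record and species counts by IUCN threat category."""
    return json.loads(_data_path("census.json").read_text())


def load_pd_loss() -> dict[str, dict[str, float]]:
    """Projected mean PD loss (%) per GCM and SSP scenario."""
    return json.loads(_data_path("pd_loss.json").read_text())
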