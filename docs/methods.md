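# Methods

This note documents the models and procedures implemented in
`phylorange`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.  All empirical numbers cited here are computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code
does not itself produce.

## Grids and geometry

All rasters are regular lon/lat grids (WGS84-style geographic
coordinates, cell-center registration, row 0 northernmost).  Distances
use the haversine formula on a sphere of radius 6,371 km — adequate at
the 4.5–500 km scales the pipeline uses.  Cell areas use the exact
spherical formula `R²·Δλ·|sin φ_top − sin φ_bottom|`, so area depends
only on the latitude band (one 2.5′ cell at the equator ≈ 21.4 km²).
Raster I/O is the plain-text ESRI ASCII grid format; polygon output is
GeoJSON.  Missing data is NaN throughout.

## Synthetic studies

The generator emulates the statistical structure of a montane-amphibian
climate-vulnerability study; one seed fully determines a study.

* **Climate.** Temperature and precipitation on a default 10°×10°
  domain at 0.1° (100×100 cells).  A Gaussian north–south ridge
  (default crest 3,800 m, half-width 2.5°) plus smoothed seeded noise
  forms an elevation proxy; temperature falls at a 6.5 °C/km lapse rate
  from a 28 °C sea-level baseline and precipitation rises with
  elevation around a 1,200 mm base.  Two variables suffice — the
  pipeline is variable-count agnostic — and no attempt is made to mimic
  real Andean topography or CMIP6 fields.
* **Scenarios.** Cell-wise map algebra (`future = current + delta`).
  Four defaults emulate a 2×2 GCM × SSP design: a warm/dry analogue
  (+3.0 °C/−120 mm and +4.5 °C/−200 mm) and a milder/wetter analogue
  (+2.5 °C/+150 mm and +3.4 °C/+80 mm), echoing the 2–5 °C warming and
  mixed precipitation deltas typical of mid-century Andean projections.
* **Virtual species.** Suitability is a product of per-variable
  Gaussian kernels scaled to a maximum prevalence in (0.9, 1.0];
  tolerances default to 1–2.5 °C and 150–400 mm.  Niche optima are
  anchored at climates observed in the 500–3,500 m elevation band,
  reflecting the mid-elevation affinity of the emulated fauna; under
  warming the suitable band therefore shifts upslope and contracts.
  The binary *truth range* of a species is the set of cells with true
  suitability ≥ 0.5.
* **Occurrences.** Records are drawn with probability proportional to
  true suitability, with an aggregation parameter (default 0.25) that
  concentrates records around a few cluster centers, mimicking
  collection effort.  The default census is 40 species; 15% receive
  1–4 records (the unmodeled path), the rest 5–60.  IUCN categories are
  drawn with probabilities 11/69 CR, 39/69 EN, 19/69 VU, matching the
  real threatened-glassfrog census proportions.
* **Phylogeny.** A constant-rate birth–death tree (birth 0.8, death
  0.3 per My) conditioned on the number of extant tips, rescaled so the
  root age is exactly 37 My and made ultrametric to 1e-9 by absorbing
  floating-point drift into terminal branches.
* **Protected areas.** Random circular patches (~1.5% of the grid
  each) accumulate until coverage reaches the target (default 35%),
  guaranteeing coverage within ±5 percentage points and contiguous
  patches rather than salt-and-pepper noise.

What the generator does **not** emulate — spatial sampling bias
correlated with accessibility, coordinate error, taxonomic ambiguity,
non-Gaussian or multimodal niches, biotic interactions, dispersal
limits, land-use change — bounds what passing tests show: recovery
results demonstrate the pipeline's correctness and its behavior under
the stated assumptions, not performance on real, messier data.

## Occurrence processing

Validation drops, with a logged per-row reason: coordinates outside
[−180, 180]×[−90, 90], points off the grid, points on no-data cells,
and duplicate records of a species within one grid cell (deduplication
at the modeling resolution; the stored coordinates are never modified,
records are merely snapped to cell centers for raster work).
Validation is idempotent.  The accessible area *M* is the union of
500 km great-circle disks around the species' record cells, clipped to
the grid; a zero buffer degenerates to exactly the occupied cells.

## Ensemble distribution models

* **Pseudo-absences:** 1,000 uniform random cells inside *M*, outside
  the occupied cells and at least 4.5 km from every record cell, on
  valid climate.  Drawn once per species; all randomness flows from a
  per-species seed derived by CRC32 from (global seed, species id), so
  each species is independently reproducible.
* **Replicates:** stratified 70/30 train/validation splits, ten per
  algorithm by default; algorithms are gradient-boosted trees, random
  forests and RBF support-vector machines with probability outputs.
  Members are deliberately shallow and slow-learning (BRT: 150 trees,
  depth 2, learning rate 0.03, 70% subsampling; RF: 200 trees, minimum
  leaf 25; SVM: C = 0.5) with balanced class weights where supported:
  presences are outnumbered ~20:1 by pseudo-absences and the underlying
  climate response is smooth, so strong regularization prevents the
  ensemble from memorizing record clusters.  These settings are the
  calibration under which the documented truth-recovery property (mean
  Jaccard ≥ 0.6 against known truth ranges) holds.
* **Evaluation:** TSS maximized over the observed prediction values on
  the held-out 30% (ties broken toward the lowest threshold — exact and
  deterministic); the omission rate is the false-negative fraction at
  that threshold.  Constant predictions score TSS 0 with a warning.
* **Ensemble:** cell-wise mean weighted by raw TSS over replicates with
  TSS > 0 (all skilled replicates, not only the best per algorithm);
  output is a convex combination of member predictions.
* **Binarization:** the "90% occurrence retention" rule — the threshold
  is the largest suitability t such that ≥ 90% of occurrence cells have
  suitability ≥ t (the 10th-percentile order statistic of ensemble
  suitability at occurrences).  Scale-free and exposed as a config
  knob.
* **Transfer:** future projections reuse the training-time weights and
  threshold, so projecting onto the training climate reproduces the
  current ensemble bit-for-bit.  Predictions are truncated (suitability
  0) where any climate variable leaves the union of the replicates'
  training-presence ranges: a niche-conservatism / no-extrapolation
  rule that keeps tree- and kernel-model extrapolation artifacts from
  inventing habitat in non-analog climates, and makes a uniform +20 °C
  scenario behave as designed (complete loss for every virtual
  species).
* **Unmodeled path:** species with fewer than five records become
  presence pixels at their record cells, current scenario only; they
  are excluded from every future product.

## Diversity, residuals, prioritization

* **PAM:** 0.5° cells anchored at integer multiples of 0.5°; a species
  is present in a coarse cell iff present in ≥ 1 fine cell within it.
  Only occupied cells are stored.
* **PD:** Faith's PD with the root path included by default (a single
  species contributes its root-to-tip distance; a full assemblage the
  total tree length); an unrooted-spanning-subtree toggle is provided.
  Extra tree tips are handled by dropping branches with no PAM species
  among their descendants, which preserves root-to-tip paths.  The
  implementation is vectorized (branch × species incidence matrix) and
  is verified in the tests against a brute-force oracle that unions
  root-to-tip branch sets.
* **LOESS:** classic 1-D local regression of PD on TD — tricube weights
  over the span-nearest neighbours, local quadratic fit, span 0.75 by
  default.  Written in-package because the procedure needs local
  degree-2 fits; ties in the integer TD predictor fall back to the
  local mean, which still reproduces exact linear relationships.
  Positive residuals mark cells holding more evolutionary history than
  richness predicts; negative residuals mark recent-speciation cells.
* **PD change:** per-cell percentage loss over cells occupied in the
  current scenario, reported as the unweighted mean plus the cell count
  (cell-averaged, not pooled; cells absent from the future PAM count as
  complete loss).
* **EDGE:** fair-proportion ED (ΣED = total tree length, an invariant
  the tests enforce to 1e-9); GE defaults CR 0.999, EN 0.667, VU 0.1 —
  a 100-year extinction-probability table shipped as editable config,
  never hard-coded; `EDGE = ln(1+ED) + GE·ln 2` exactly.  The per-cell
  aggregator defaults to the maximum EDGE among species present
  (locating individual evolutionarily unique species); mean and sum are
  available, and ED can be mapped instead of EDGE.

## Conservation accounting

Contraction = (current − future)/current × 100, computed from
fine-resolution ranges (not the coarse PAM), capped above at 100 and
unbounded below (expansions are negative).  Complete loss ⇔ zero future
area ⇔ contraction 100.  Genus = leading token of the species
identifier; genus means include complete-loss species by default, with
an exclusion mode provided because published genus aggregates are not
always consistent on this point.  Protected overlap is the
area-weighted percentage of a range inside the protected mask, computed
against the future range of each scenario (current range for the
current scenario).

## Problem sizes and numerical choices

The default study profile is 40 species on a 100×100 grid with four
future scenarios.  Tests and the acceptance script run it with two
replicates per algorithm (6 models/species, the reduced-replication
profile); the full protocol (10 per algorithm, 30 models) is the
library default for analyses.  Ultrametricity tolerance 1e-9; TSS
threshold search over observed values only; LOESS requires ≥ 10
occupied cells and ≥ 2 distinct TD values, and errors loudly on
degenerate inputs rather than guessing.  Seeds derived from the global
seed stay below 2³¹.

## Limitations

No MaxEnt/GAM/GLM members, no hyperparameter search, no spatial-block
cross-validation, no dispersal constraints or land-use overlays, no
null-model standardized effect sizes for PD, and no EDGE2 variant.  The
GE encoding (probability vs. ordinal rank) is configurable because
published EDGE tables rarely state it; rankings depend on that choice.
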