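# phylorange

Climate-change range projection and phylogenetic conservation
prioritization for threatened Neotropical glassfrogs (Centrolenidae) —
and, more generally, for any montane fauna whose occurrence records,
climate layers and dated phylogeny can be put on a common grid.

Glassfrogs are a largely Andean radiation; 69 species are IUCN-listed as
threatened (CR/EN/VU).  Because montane species track their climatic
niches upslope as temperatures rise, projected warming reshapes not only
where species can persist but how much *evolutionary history* each place
holds.  This package implements the full analysis chain that turns point
records, climate scenarios and a time-calibrated tree into conservation
priorities:

1. **Occurrence processing** — coordinate validation, per-grid-cell
   deduplication, and the accessible area *M* (a 500 km great-circle
   buffer around records) that bounds model calibration.
2. **Ensemble species distribution models** — 1,000 random
   pseudo-absences per species (≥ 4.5 km from records), three algorithms
   (boosted regression trees, random forests, support-vector machines),
   ten 70/30 subsampling replicates each, scored with the True Skill
   Statistic (TSS = sensitivity + specificity − 1) and the omission
   rate; replicates with positive TSS are averaged with TSS-proportional
   weights.  Ensembles are binarized at the suitability threshold that
   retains 90% of occurrence cells and transferred onto future climate
   scenarios (with projections truncated outside the occupied climate
   envelope).  Species with fewer than five records are rasterized
   directly and never projected.
3. **Spatial phylodiversity** — binary ranges stacked into a 0.5°
   presence–absence matrix (PAM); per-cell taxonomic diversity (TD,
   species counts) and Faith's phylogenetic diversity
   (PD = Σ branch lengths of the rooted subtree spanning the cell's
   species); LOESS residuals of PD ~ TD; per-cell percentage PD loss
   between scenarios.
4. **EDGE prioritization** — fair-proportion Evolutionary
   Distinctiveness (ED, in My), Global Endangerment (GE) as a 100-year
   extinction probability per IUCN category, and
   `EDGE = ln(1 + ED) + GE·ln 2`, rasterized per PAM cell.
5. **Conservation accounting** — spherical range areas, contraction
   percentages, complete-loss classification, genus summaries,
   protected-area overlap, and zonal species richness.

A first-class synthetic-data module generates seeded studies with known
truth — Andes-like climate fields, Gaussian-niche virtual species,
clustered occurrence sampling, birth–death ultrametric trees, scenario
deltas and patchy protected areas — so the whole pipeline is testable
end-to-end without any download.

## Worked example

```python
import phylorange as pr

cfg = pr.PipelineConfig().compact(2)   # 40 species, 100x100 grid, 6 models/species
study = pr.run_study(cfg, seed=1)
print(round(study.summary()["mean_tss"], 2))
print(round(study.summary()["mean_truth_jaccard"], 2))
print(round(study.pd_changes["gcmWarmDry_ssp370"].mean_loss_percent, 1))
print(study.scores["EDGE"].idxmax())
```

prints

```
0.82
0.67
26.1
GenusA species_001
```

meaning: the replicate models average a TSS of 0.82 on held-out data;
the modeled current ranges overlap the known truth ranges with a mean
Jaccard index of 0.67; the warm/dry high-emissions scenario erases
26.1% of phylogenetic diversity per occupied 0.5° cell on average; and
the named virtual species is the top EDGE conservation priority of this
simulated fauna.

The bundled reference tables for the real glassfrog fauna are available
through `phylorange.datasets` — for example
`pr.classify_loss(datasets.load_contraction_long())` finds the 12
species projected to lose all climatic suitability under at least one
scenario, 6 of them under every scenario.

A thin CLI wraps the same functions:

```bash
phylorange simulate --seed 1 --out fixture/
phylorange run --seed 1 --replicates 2 --out results/
phylorange edge-scores --tree fixture/tree.nwk --categories cats.csv
```

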