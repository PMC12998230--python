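# limnoecol

Absolute-abundance microbial biogeography for large stratified lakes.

Amplicon surveys alone only see *composition*: a taxon at 10 % relative
abundance may be ten times more numerous in one sample than another. This
package couples 16S ASV profiles to flow-cytometry cell counts so that every
downstream statistic — dissimilarity, clustering, assembly inference, trait
abundance — operates on cells/ml rather than proportions. It is aimed at
microbial ecologists analysing depth- and season-structured surveys of large
lakes (or any system with paired amplicon + cytometry data), and ships a
seeded synthetic-data generator so the whole stack is testable without any
external download.

## What it computes

* **Cell quantification** (`limnoecol.flow`) — per-event (FSC-H, FL1-H)
  tables are threshold-filtered, polygon-gated, and converted to
  concentrations: `cells/ml = n_gated / (V_eff · 10⁻³) · dilution`, with
  default effective volume 42.5 µl and 20× dilution, averaged over stain
  replicates.
* **Table hygiene** (`limnoecol.features`) — organelle (mitochondria /
  chloroplast) removal, negative-control contaminant removal (a taxon is
  dropped when its relative abundance peaks in a blank), replicate merging
  by summed reads, and the relative→absolute transform
  `A(t, s) = p(t, s) · cells_per_ml(s)`.
* **Phylogeny** (`limnoecol.phylo`) — newick I/O, re-rooting at the MRCA of
  the Archaea, pruning of anomalous tips with root-to-tip height > 2, and
  per-branch abundance aggregation.
* **Diversity** (`limnoecol.diversity`) — Hill numbers `^qD`, analytic
  (hypergeometric) rarefaction, and the UniFrac family. The central
  statistic is the absolute-abundance generalized UniFrac

  ```
  GU^A_α(r, s) = Σᵢ bᵢ (Aᵢ+Bᵢ)^α |Aᵢ−Bᵢ|/(Aᵢ+Bᵢ) / Σᵢ bᵢ (Aᵢ+Bᵢ)^α
  ```

  with per-branch masses in cells/ml, so identical compositions at
  different total biomass are at nonzero distance (two-tip star, totals
  1:2 → exactly 1/3 for every α), while equal totals reduce it to the
  ordinary relative-abundance statistic.
* **Community structure** (`limnoecol.structure`) — UPGMA with a
  deterministic lexicographic tie-break, dendrogram cutting, PCoA,
  one-factor PERMANOVA, a PERMDISP-style dispersion test, and Mantel
  (Spearman) decay correlations against great-circle distance or |Δdepth|.
* **Assembly processes** (`limnoecol.assembly`) — phylogenetic-bin null
  models: tips are partitioned into monophyletic bins (min 24 taxa, max
  within-bin distance 0.5), and each sample pair × bin is classified by
  βNRI (label-shuffle standardized βMPD; |βNRI| > z₀.₉₇₅ ⇒ selection) and
  RC_Bray (Raup–Crick-standardized Bray–Curtis; |RC| > 0.95 ⇒
  dispersal) into heterogeneous selection, homogenizing selection,
  dispersal limitation, homogenizing dispersal, or drift, weighted by bin
  abundance and aggregated within/between sample groups.
* **Trait inference** (`limnoecol.traits`) — FAPROTAX-dialect databases of
  taxonomy glob patterns, evaluated against absolute abundances so trait
  values are in predicted cells/ml.
* **Synthetic data** (`limnoecol.simulate`) — seeded generator of tree,
  counts (duplicate replicates + blanks), taxonomy, metadata, flow events
  and a trait database with planted truth: three depth-month groups over a
  cosmopolitan core, September upwelling that mixes deep taxa into surface
  samples and plants novel rare (<0.01 %) taxa carrying otherwise-absent
  traits, temperature-coupled cell densities, and station-blocked deep taxa.

## Worked example

```bash
limnoecol run --seed 1 --out run_out
```

runs simulate → gate → clean → dist → cluster → PERMANOVA/dispersion →
decay → assembly → Hill → traits and writes `run_out/report.json` plus CSV
artifacts. The same stages are available piecewise (`limnoecol simulate`,
`gate`, `clean`, `dist`, `cluster`, `assembly`, `traits`, `report`) and
compose to byte-identical outputs. From a library session:

```python
from limnoecol.pipeline import PipelineConfig, run
report = run(PipelineConfig(seed=1, out_dir="run_out", n_null=200))
print(report["permanova"])   # {'F': ..., 'R2': 0.6509..., 'p': 0.001, ...}
print(report["decay"]["May"])
```

On the default synthetic study (seed 1, 300 taxa, 8 stations × 3 depths ×
2 months, duplicate replicates) this prints, among others:

| quantity | value | meaning |
|---|---|---|
| PERMANOVA R² (3 depth-month groups) | 0.65 | groups explain most GU^A₀.₅ variance |
| distance-decay ρ (May) | 0.04 | similarity unrelated to geographic distance |
| depth-decay ρ (May) | −0.82 | similarity falls steeply with Δdepth |
| Spearman cells vs temperature | 0.95 | biomass tracks thermal structure |
| drift, within Deep | 53 % | stochastic turnover dominates the hypolimnion |
| flow recovery error | 0.7 % | gated counts reproduce true cells/ml |

The planted Shallow May / Shallow September / Deep partition is recovered
exactly by the UPGMA cut at k = 3 (upwelling samples excepted — they are
genuine deep/surface hybrids), and the upwelling-only traits (sulfate
respiration, methanotrophy) are non-zero only in upwelling samples.

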