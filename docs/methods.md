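# Methods

This note documents the models, defaults and numerical choices behind
`limnoecol`, and what the synthetic-data generator does and does not
emulate.

## Absolute abundance

Relative ASV abundances are multiplied by the sample's flow-cytometry cell
concentration, giving taxon abundances in cells/ml. Concentrations come
from per-event tables: events must exceed FSC-H 100 and FL1-H 400 (strict
inequalities), then fall inside a user-supplied polygon gate evaluated
after per-axis transform (`linear` or `log10`; containment is
boundary-inclusive, which coincides with the even-odd rule for the simple
polygons we require). Concentration per stain replicate is
`n_gated / (V_eff · 10⁻³ ml) · dilution` with defaults V_eff = 42.5 µl and
dilution 20×; stain replicates (up to three) are aggregated by arithmetic
mean with CV = sd/mean (ddof = 1). Zero gated events yields concentration
0 with a warning flag rather than an error, since blanks legitimately gate
to zero. No compensation or gate learning is attempted; real instrument
gates should be supplied as vertex lists.

## Count-matrix hygiene

* Organelle removal matches the tokens "mitochondria"/"chloroplast"
  case-insensitively against whole rank values; empty ranks never match.
* The contaminant rule compares, per taxon, the maximum per-column relative
  abundance over negative controls against the maximum over true samples
  and removes the taxon when the control side is strictly larger. Max-vs-max
  is the most conservative comparator consistent with removing taxa that
  peak in blanks; relative abundance is computed within raw (pre-merge)
  columns because controls have no replicates.
* Replicates are merged by summing reads; groups spanning different
  station/depth/month combinations are rejected. Merging then taking
  proportions is not the same as averaging per-replicate proportions unless
  depths are equal; the merged-counts route is canonical here.
* "Rare" means 0 < relative abundance < 10⁻⁴ (strict on both sides),
  applied post-merge.

## Distances and ordination

The generalized UniFrac ratio is computed over every non-root branch i with
length b_i and per-sample descendant masses A_i, B_i:

d = Σ b_i (A_i+B_i)^α |A_i−B_i|/(A_i+B_i) / Σ b_i (A_i+B_i)^α,

skipping branches with zero combined mass. In absolute mode the masses are
cells/ml. The ratio form keeps d in [0, 1], reduces exactly to the
relative-mode statistic when sample totals are equal, and makes pure
biomass differences visible (identical composition at totals 1:2 gives
d = 1/3 for every α, since |A−B|/(A+B) = 1/3 on every branch). Branch
lengths are not rescaled. α defaults to 0.5; α = 1 is the classic weighted
statistic, and the unweighted variant uses presence/absence
(XOR/OR of branch occupancy).

UPGMA uses the unweighted-average cluster distance with a deterministic
tie-break (the candidate pair whose smallest leaf ids sort first), making
the merge history invariant under input order; cutting undoes the k−1 last
merges. PCoA double-centers the squared distances; axes with negative
eigenvalues are reported but excluded from coordinates. PERMANOVA is the
one-factor decomposition (SS_total = Σ_pairs d²/n, SS_within analogous per
group), R² = 1 − SS_w/SS_t, with p = (1+B)/(1+N) under label permutation —
single-factor because the headline design is a single depth-month grouping.
The dispersion test measures distances to group centroids in full PCoA
space, subtracting squared imaginary-axis components (floored at zero), and
permutes those distances; centroids (not spatial medians) are used, the
simplest defensible variant. Mantel decay correlations are Spearman over
upper-triangle pairs with joint row/column permutation of the covariate;
great-circle distances use the WGS84 mean radius 6 371.0088 km. All
permutation tests take explicit seeds; defaults are 999 permutations.

## Assembly-process inference

Tips are partitioned into phylogenetic bins: seed bins are the maximal
monophyletic clades with within-clade maximum cophenetic distance ≤ ds
(default 0.5); bins below the size limit (default 24) are merged, smallest
first, into the bin at smallest mean inter-bin distance (final merges may
exceed ds). Fewer tips than the size limit yields a single bin with a
warning.

Per sample pair and bin present in both samples:

* βMPD = f_Aᵀ D f_B with within-bin proportion vectors and the cophenetic
  submatrix D (self-terms included, d_ii = 0). βNRI standardizes βMPD
  against nulls built by shuffling taxon labels across the bin's own tips;
  a zero-variance null returns 0 with a degenerate flag. Shuffling within
  the bin (not across the tree) matches the bin-based framework's intent of
  testing relatedness structure at the clade scale.
* RC_Bray compares observed Bray–Curtis on bin counts with nulls that
  preserve each sample's within-bin richness and read total: taxa are
  drawn without replacement with probability ∝ occurrence frequency
  (Gumbel top-k), reads allocated multinomially ∝ mean relative abundance.
  RC = 2·[(#{null<obs} + ½#{null=obs})/n_null] − 1 ∈ [−1, 1].

Classification: βNRI > z* → heterogeneous selection; βNRI < −z* →
homogenizing selection; otherwise RC > 0.95 → dispersal limitation,
RC < −0.95 → homogenizing dispersal, else drift. z* is the standard normal
quantile of the confidence parameter (0.975 → 1.959964) rather than a
hard-coded constant. Bin weights are the pair-mean bin relative abundance
renormalized over bins present in both samples; pair fractions aggregate by
unweighted mean within each group and between each unordered group pair.
One randomization per null iteration serves every sample pair — the
standard construction, and what makes the batch path O(n_null) rather than
O(n_null · n_pairs). The default n_null is 1000; the test suite and the
acceptance script run at 200, which changes null quantiles by ~√5 less
Monte-Carlo precision but no systematic shift.

RC_Bray is deliberately sensitive at high read depth: compositional
variance beyond what richness- and abundance-preserving resampling explains
is read as a dispersal signal. Consequently the neutral-drift reference in
the scenario generator is literal multinomial sampling from a shared pool
(the null's own data-generating process), not a Dirichlet overdispersion.

## Diversity

Hill numbers use ^qD = (Σ p_i^q)^{1/(1−q)}, with the q = 1 case evaluated
as exp(Shannon) (branch taken within 10⁻⁹ of q = 1); zeros are excluded and
columns renormalized. Rarefaction is the analytic hypergeometric
expectation E[S_m] = Σ_i (1 − C(N−N_i, m)/C(N, m)) evaluated via log-gamma;
no extrapolation beyond observed depth and no asymptotic richness
estimators.

## Trait inference

The parser targets the common FAPROTAX dialect: group headers (name +
`key:value` metadata), one member pattern per line, `add_group:` unions of
earlier groups (forward references are parse errors with line numbers), and
`#` comments. Patterns are anchored, case-sensitive globs where `*` crosses
rank separators; lineages are rendered as semicolon-joined ranks without
prefixes. Traits are summed over matching taxa in cells/ml; a taxon may
contribute to many traits; coverage is the fraction of matrix taxa with at
least one trait. A small curated fixture database (photoautotrophy, aerobic
ammonia oxidation, sulfate respiration, methanotrophy, plus a methylotrophy
add_group example) ships for tests; real databases are user-supplied.

## The synthetic study

Defaults: 300 taxa, 8 stations × depths {E, M, B} × months {May,
September}, duplicate biological replicates, two blank controls, read
depths log-uniform in [8 000, 80 000] (matching the post-filter range of
real surveys of this design), six planted contaminants, four organelle
taxa, one upwelling station.

The tree is built from tight clades (max tip-to-tip distance rescaled into
[0.25, 0.40], below the 0.5 binning distance) joined by a backbone whose
stems keep clades > 0.6 apart while root-to-tip heights stay below the
long-branch pruning threshold of 2. Clades carry coherent taxonomy
(Actinobacteria, Alphaproteobacteria, Bacteroidia, Cyanobacteriia,
Anaerolineae, archaeal Nitrososphaeria — the last always present so the
MRCA-of-Archaea rooting is well defined).

Community pools: lognormal base abundances; ~30 % of taxa are a
cosmopolitan core with no group effect; the rest get a multiplicative
e^{group_effect} boost in their home group (clade-biased: Bacteroidia →
Shallow May, Cyanobacteriia → Shallow September, Anaerolineae and
Nitrososphaeria → Deep). The deep pool is shared across months; E and
May-M samples draw from their month's surface pool, September-M samples
from the deep pool (below the thermocline at average station depth, and
with correspondingly cold temperatures). Per-sample composition is
Dirichlet(drift_concentration · pool); replicates share it and differ only
by taxon-level lognormal jitter (cv 0.05) and multinomial read sampling.

Upwelling (September surface at the configured stations) replaces the
composition with mix·deep + (1−mix)·surface and plants `rare_novel_taxa`
sample-specific taxa at proportions U(1, 4)·10⁻⁵ — sized so realized
relative abundances stay below the 10⁻⁴ rare threshold at the default
depths — annotated as *Desulfuromonas* (sulfate respiration) and
Methylomonadaceae (methanotrophy), lineages absent elsewhere. Hypolimnion
dispersal limitation is planted by restricting blocks of
`dispersal_block_size` deep taxa to random half-station subsets (0
disables blocking). True cell concentration is
5·10⁵ + 1.5·10⁵·T(°C) + 5 % noise, giving warm September surfaces ~3.5·10⁶
and the hypolimnion ~1.1·10⁶ cells/ml and a strong rank correlation with
temperature. Flow events per sample are three stain replicates of a
lognormal stained cluster inside the packaged gate (Poisson count equal to
the analytic inverse of the concentration formula) plus low-channel debris
outside it. Negative controls contain only the contaminant taxa —
extraction blanks dominated by kit contaminants — which keeps the
contaminant filter's ground truth exact.

What the generator does *not* emulate: sequence-level error and chimeras,
taxonomy misassignment, copy-number variation, within-bin phylogenetic
selection gradients in the default dataset (selection signals are exercised
by the dedicated scenario generators), temporal succession, and any spatial
autocorrelation beyond station blocking. Passing tests therefore certify
the statistical machinery, not the generator's fidelity to any particular
lake.

Scenario generators for the assembly classifier plant one dominant process
each: shared concentration of abundance on a phylogenetically tight
subclade per bin (homogenizing selection); two sites with phylogenetically
random, exclusive taxon blocks (dispersal limitation; `block_strength`
scales exclusivity); and multinomial sampling from one shared pool
(drift).

## Pipeline

Stages are pure file-to-file functions over a run directory; the CLI
subcommands call exactly those functions, so piecewise and monolithic runs
are byte-identical. A single seed fans out per stage via
`(seed · 100003 + 7919 · stage) mod 2³¹`, recorded in the report, so stage
reordering never silently changes results. Reports echo all analysis
parameters and their hash (filesystem paths excluded, so identical analyses
in different directories produce identical reports). Problem sizes in the
shipped tests and the acceptance script (120–300 taxa, 3–8 stations,
100–200 null iterations) were chosen as the smallest sizes at which each
statistical property is comfortably measurable.

## Known limitations

* The PERMANOVA is single-factor; no dbRDA/variance partitioning.
* RC_Bray inherits the framework's depth sensitivity (above); comparisons
  across datasets with very different read depths should be rarefied or
  interpreted cautiously.
* The absolute UniFrac trusts the cytometry scaling; systematic gating
  error propagates multiplicatively into every distance.
* FCS binary parsing is out of scope; events arrive as CSV exports.
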