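# Methods

This note records the models, conventions and numerical choices behind
`metanetdiff`, and what the synthetic-study generator does and does not
emulate.

## Synthetic study generator (`synth`)

The generator emulates a two-diet (ad libitum vs dietary restriction) fly
metabolome study: a full factorial of diets × ages × tissues × biological
replicates (default 6, as independent rearing populations) each measured as
technical replicates (default 3), on two chromatography columns whose m/z
ranges (AE 86.0605321–1738.34568 Da, C18 85.0279778–1976.50254 Da) are
sampled uniformly.

Log2-scale value of feature *i* in biological sample *s*:

    y_is = base_i + beta_diet_i·[diet=DR] + beta_age_i·age_s + delta_{batch(s)}
           + module term + N(0, sigma_bio²)

with `base_i ~ U(10, 20)` log2 units, `sigma_bio = 0.5`. Technical
replicates add `N(0, sigma_tech²)` noise (0.1; 1.2 for planted low-SNR
features, putting their SNR ≈ 12 under the filter's threshold of 20).
Values are exponentiated to the intensity scale.

* **Effects.** A fraction of features gets diet effects `N(0, effect_size_sd)`
  and, independently, age effects expressed as a per-day slope whose total
  change over the age span is `N(0, effect_size_sd)`. Among doubly-affected
  features, `frac_reversal` get `sign(beta_diet) = −sign(beta_age)` (DR
  pushes the metabolite back toward its young level); the rest get
  concordant signs.
* **Batch effects** are per-batch scalar location shifts
  `N(0, batch_shift_sd)` common to all features, assigned round-robin over
  biological replicates so every design cell is batch-balanced.
* **Modules.** A module of size *m* with correlation *r* loads
  `sqrt(r_eff)` on a shared per-sample latent factor and `sqrt(1 − r_eff)`
  on idiosyncratic noise, so the expected within-module Pearson correlation
  is `r_eff` where the module is active (`DR-only`, `AL-only`, or both). A
  single latent factor cannot make *all* pairs negative, so
  `both-opposite-sign` flips the loading sign of half the members in AL:
  cross-half pairs reverse correlation sign between diets. The optional
  `corr_age_trend` makes `r_eff` increase with age under DR and decrease
  under AL — the generator's analogue of aging eroding network structure
  under full feeding only. Modules are drawn from mean-unaffected features
  so correlation structure is not confounded with mean shifts.
* **Missingness** is MCAR at the *biological-sample* level: a dropped
  (feature, sample) cell is missing in all of that sample's technical
  replicates, as a detection-limit dropout would be. A cell-level mask
  would almost never survive technical-replicate averaging and would leave
  the missingness filter and imputation untested. Intensity-dependent
  missingness is out of scope.
* **Outlier samples** (optional) add `N(0, outlier_sd·sigma_bio)`
  feature-wise noise to whole biological samples, destroying their
  correlation to the rest — the signature the connectivity-based outlier
  detector looks for.

Everything is drawn from one `numpy` generator seeded by the config, so
identical (config, seed) gives bit-identical tables and ground truth.

What passing tests on this generator do **not** show about real data:
there is no retention-time or adduct structure linking features of one
metabolite, no heteroscedastic or intensity-dependent noise, no drift
within batches, and the latent-factor modules are an idealisation of
pathway co-regulation. Recovery results are therefore upper bounds on what
the same sample sizes would give in a real study.

## Quality control (`qc`)

The chain is log2(x + 1) transform → outlier-sample removal → SNR filter →
technical-replicate collapse (mean of observed replicates) → missingness
filter (> 10% missing biological samples) → imputation → per-feature mean
centring (no rescaling). Choices:

* **Log base 2, pseudocount 1** (both configurable); the source protocol
  states neither.
* **Outlier samples** use the standardized sample-network connectivity:
  adjacency `(1 + cor)/2` over complete features, connectivity
  `k_i = Σ_{j≠i} a_ij`, `Z_k = (k − mean k)/sd k`, flag below −3. Constant
  connectivities (sd = 0) flag nothing. In the pipeline, flagging any
  technical replicate removes the whole biological sample.
* **SNR** = feature mean / sigma_tech, computed on the log scale (a raw
  scale mode exists), with sigma_tech the *mean* across biological samples
  of the sd among that sample's technical replicates; a pooled-variance
  mode is available since "average standard deviation of each technical
  replicate" is ambiguous between the two. Noiseless features (sigma = 0)
  are kept.
* **Imputation** default is feature-kNN: each missing cell is predicted by
  the k = 10 features most correlated with the target (pairwise-complete
  correlations), each neighbour's value mapped through the fitted
  neighbour→target regression line, combined by an |r|-weighted mean. For
  two perfectly correlated features this reproduces the regression-line
  value exactly. An `em_regression` mode iterates multivariate regression
  of each incomplete feature on its best correlates to tolerance 1e-6.
* **Quantile normalization** (used before age-split correlation analyses)
  replaces each sample's order statistics by the across-sample mean order
  statistics, with ties receiving the value interpolated at their average
  rank.

## Effect models (`models`)

Diet is coded AL = 0 / DR = 1 and age in days, so slope signs read as
"increases under DR / with age". Fits are closed-form OLS with a two-sided
t-test on the slope; a constant response returns β = 0, p = 1, a perfectly
sloped response p = 0. The reversal analysis contrasts the diet effect at
one age (default the oldest) with the age effect on AL between the
youngest and oldest ages; both slope vectors are BH-adjusted marginally at
FDR 0.025 (each test at 0.025, not a joint FDR) and doubly-significant
features are classified by the sign product. Venn comparisons of per-age
diet-responsive lists use raw P < 0.01 by default.

**Batch adjustment** is parametric empirical-Bayes ComBat (delegated to
scanpy's implementation, which matches the reference R `sva::ComBat`),
preserving supplied covariates; categorical covariates are passed as k−1
numeric dummies because a full one-hot coding alongside the batch design
is singular. EB shrinkage deliberately leaves a fraction
`d²/(n·t² + d²)` of each feature's estimated batch offset in place — with
a location-only batch effect this is about half of the batch-mean sampling
noise, at any realistic sample size. Where complete within-data batch-mean
removal is the goal (e.g. before pooling batches into one correlation
network), `eb=False` gives the unshrunk location/scale adjustment
(limma-style), which equalises per-feature batch means exactly. The
pipeline default stays `eb=True` as the faithful ComBat.

## Differential pairs (`paircorr`)

The ANCOVA is asymmetric, so a convention fixes the orientation: the
higher-variance feature is the covariate, ties broken toward the first
argument (by feature id in the screen). The interaction F is computed in
closed form from per-diet sums of squares — full model = separate slopes
and intercepts per diet, reduced = common slope — with df (1, n − 4),
vectorised over all pairs via per-diet Gram matrices so the all-pairs
screen is feasible without pre-filtering. The mean gate (unadjusted diet
p > 0.05) restricts the screen to mean-invariant features; BH-FDR is
applied across tested pairs. An |r_AL − r_DR| pre-filter and a seeded
`max_pairs` cap exist but default off: selecting extreme pairs before BH
inflates the realised false-discovery rate under the null. A Fisher
r-to-z difference test is provided as a descriptive cross-check.

## Networks (`network`)

* **Difference matrix**: the signed-square form
  `d_ij = (½|sign(c)c² − sign(c′)c′²|)^(β/2)`, β even (default 6).
* **Constancy matrix**: default `min(|c|, |c′|)²^(β/2)` for sign-concordant
  pairs, 0 otherwise. The exact algebraic mirror of the difference matrix
  (sum in place of difference) is available as `method="signed-sum"`, but
  it assigns half-strength constancy to pairs strong in only *one*
  condition, so clustering it recovers condition-specific modules —
  contradicting what a "preserved network" analysis is for. The two forms
  agree exactly on sign-flipped and on equally-correlated pairs.
* **TOM**: standard unsigned topological overlap with unit diagonal.
* **Module extraction**: average-linkage on 1 − TOM, cut at a grid of merge
  heights. TOM dissimilarities of sparse difference matrices occupy a
  narrow band near 1, so for scoring the dissimilarity is affinely
  rescaled to [0, 1]; each cluster with ≥ `min_size` members (and at most
  half of all features) gets a cluster-level silhouette
  `(b − a)/max(a, b)` (a = mean within dissimilarity, b = mean
  dissimilarity to non-members), clusters scoring ≥ 0.05 are accepted, and
  the cut maximising the size-weighted accepted score wins. Size-weighting
  prefers a complete module over its tighter core; the 0.05 floor sits an
  order of magnitude above the scores background clusters reach in this
  generator's conditions. Unassigned features are grey; colours follow the
  WGCNA palette by decreasing size.
* **Module dispersion test**: observed `sqrt(mean d_ij²)` over in-module
  pairs against a null that redraws the condition split of the pooled
  samples; p = (1 + #{null ≥ obs})/(1 + n_perm). **Caveat:** when applied
  to modules clustered from the *same* data, the test conditions on the
  module having been selected for high dispersion and is anti-conservative
  — at small n (6 biological replicates per cell) pure-noise clusters can
  pass. It is still effective at demoting the sampling-noise "shadow" that
  a *preserved* module casts in the estimated difference matrix (noise in
  ĉ² is amplified by 2c, so strongly correlated preserved pairs show
  elevated d̂), because that structure is label-exchangeable. Planted-module
  recovery is therefore benchmarked at 24 samples per condition.
* **Correlation shift test**: difference in mean off-diagonal correlation,
  with significance from the same condition-label permutation null when the
  sample matrices are available (exact and calibrated). A per-feature
  sign-flip null is kept as a fallback for adjacency-only input, but the
  per-feature mean-correlation differences are strongly cross-correlated,
  the flips ignore that, and the fallback is anticonservative (~17% type-I
  at nominal 5% in simulation) — its p is descriptive only.
* **Differential/similar feature selection**: per-pair correlation
  significance from the r→t transform at level 0.01 per condition; a
  feature is *differential* if some pair is significant in exactly one
  condition and none in both, *similar* if some pair is significant in
  both with the same sign. These subsets feed DiffCoEx and SimCoEx
  clustering respectively, as in the source analyses. The rule behind the
  original feature counts is not published; this is a documented guess.
* The |r| > 0.5 edge-list threshold is export-only rendering, not
  inference.

## Enrichment (`enrich`)

Pathway scoring replaces the mummichog activity-network permutation
machinery with plain hypergeometric over-representation on user-supplied
metabolite sets: simpler and exactly testable against a combinatorial
oracle. Features map to metabolites through adduct offsets (M+H +1.007276,
M+Na +22.989218, M+K +38.963158, M−H −1.007276, M+ −0.000549 Da) within a
relative ppm tolerance (default 10); all candidate matches are kept, and
feature→metabolite multiplicity is collapsed to unique metabolites before
counting so one metabolite matched by several features counts once.
Per-condition enriched sets (q ≤ 0.05) are summarised in a
conditions × sets frequency table.

## Pipeline

One global seed fans out to fixed per-stage offsets (`seed·1009 + offset`,
kept below 2³¹), so stages are independently re-runnable and the whole
replay is byte-deterministic. The manifest records per-stage feature/sample
counts in and out; each stage's output count equals the next stage's input
count. The network stage caps the feature set (default 600, seeded
subsample) — correlation-matrix work is quadratic and the module analyses
are about structure recovery, not exhaustiveness.

## Problem sizes

Default study: 2000 features, 2 diets × 3 ages × 1 tissue × 6 biological ×
3 technical replicates, 2 batches, 5% MCAR, 5% low-SNR, four planted
modules. Recovery experiments use sharper, single-purpose designs: reversal
recovery at 1200 features with half the features affected per predictor and
2-log2-unit effect sd; module contrast at 500 features, 24 samples per
diet, one DR-only and one both-condition module (r = 0.7, size 40);
calibration runs at 50–200 features with 200 replicates. These sizes keep
any single experiment under about a minute while leaving the Monte-Carlo
error well inside the asserted margins.

## Known limitations

* Hierarchical-clustering module extraction is a simplification of the
  dynamic hybrid tree cut; extremely nested or overlapping modules are out
  of scope, as are eigenmetabolite summaries and module–trait correlation.
* The dispersion permutation test is anti-conservative for data-selected
  modules (see above); a split-sample design would fix this but is
  underpowered at the emulated replication level.
* Annotation is m/z-only: no retention-time, isotope-pattern or MS/MS
  evidence, and ambiguous matches are all retained.
* The EM imputation mode is a regression-iteration approximation, not a
  full EM with explicit covariance model.
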