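# Methods

`cupscore` implements a pattern-discovery and scoring workflow for bulk
tumour transcriptomes built around a 13-gene panel of cuproptosis
regulators (FDX1, LIPT1, LIAS, DLD, DLAT, PDHA1, PDHB, DBT, GCSH, DLST,
SLC31A1, ATP7A, ATP7B). The pipeline is: multi-cohort preprocessing →
consensus clustering of samples on the panel → pairwise differential
expression between the resulting patterns → extraction of the
pattern-defining ("overlap") genes → prognostic filtering → a PCA-based
per-sample score (the CupScore) with survival stratification. Mutation,
copy-number and protein-interaction summaries sit alongside.

## Preprocessing

FPKM input is converted to TPM by per-sample renormalisation
(`TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶`, so each pre-log column sums to
10⁶ exactly) and log2(x+1)-transformed; the pseudocount of 1 is the common
convention for bulk expression.

Cross-cohort technical differences are removed with ComBat in its
parametric empirical-Bayes form without covariates: genes are standardised
against a batch-design fit, per-batch additive (γ) and multiplicative (δ²)
effects are estimated and shrunk toward cross-gene parametric priors
(normal for γ, inverse-gamma for δ²) by the standard fixed-point updates,
and the data are back-transformed. The implementation matches
Bioconductor `sva::ComBat` to ~1e-5 on shared fixtures. Two properties of
the EB form are worth knowing: the shrinkage deliberately leaves a
residual batch effect at the scale of the batch-mean estimation noise
(≈ σ·√(2/n)/2 per gene — about 0.1 log2 units at n=50/batch, identical in
sva), and re-applying the correction therefore nudges values slightly
rather than acting as an exact identity. Batches of one sample are
rejected; constant genes pass through unadjusted. Whether correction runs
jointly across all cohorts or per platform is a pipeline flag; joint is
the default.

## Consensus clustering

Samples are clustered on the regulator panel by subsampling consensus:
for each candidate k, `n_resamples` (default 1000) draws of
⌈0.8·n⌉ samples are clustered and the consensus entry for a sample pair
is the fraction of co-clustered draws among co-sampled draws. The base
clusterer is agglomerative with average linkage on 1 − Pearson correlation
between sample profiles (k-means is available as an alternative). Genes
are median-centred before the distance is computed — with only 13 panel
genes, raw profile correlations are dominated by the shared per-gene
baseline and centring is what lets the pattern differences drive the
clustering (it is also the documented recommendation of the reference
consensus-clustering tool for expression data).

k is selected by the proportion of ambiguous clustering (PAC: mass of the
consensus-entry CDF between 0.1 and 0.9), with two refinements that the
bare argmin needs in practice:

* k values whose consensus partition contains a cluster smaller than 5% of
  the cohort are disqualified — with average linkage these partitions are
  stable outlier-peels, not structure, and their PAC can be spuriously
  tiny;
* among the remaining k within 0.01 PAC of the minimum, the largest is
  chosen. A merge of two internally stable clusters is itself perfectly
  stable (PAC ties at ~0 below the true k), whereas over-splitting a
  homogeneous cluster is subsample-dependent and inflates PAC by an order
  of magnitude more than the 0.01 tolerance, so the rule keeps the finest
  unambiguous partition without over-clustering.

The delta-area series of the consensus CDF is reported alongside. Final
labels come from an agglomerative cut of 1 − consensus at the chosen k and
are relabelled by ascending mean panel expression, so the last letter
("C" at k = 3) is always the pattern with the highest regulator
expression.

## Differential expression and the overlap pool

Two-group comparisons use an empirical-Bayes moderated t: gene-wise pooled
variances are shrunk toward a scaled-inverse-χ² prior whose hyperparameters
(d0, s0²) are estimated by moment matching on log s² with
digamma/trigamma inversion; the moderated statistic is referred to a t
distribution with d0 + d degrees of freedom and BH-adjusted. The
implementation reproduces Bioconductor `limma` to ~5e-13 on shared
fixtures; the d0→0 and d0→∞ limits (ordinary t; common-variance z) are
asserted in tests.

Pattern DEGs are discovered pairwise between all cluster pairs with the
default filter |log2FC| > 0.7 and p < 0.05. The CupScore gene pool uses a
stricter, separate rule: "overlap" genes are those with BH-adjusted
p < 0.001 in **every** pairwise comparison (intersection semantics; union
is available as an option). The two-threshold split — permissive raw-p
rule for pairwise discovery, strict adjusted-p intersection for the score
pool — keeps exploratory pattern annotation broad while restricting the
signature to genes that separate all patterns at once.

## Survival machinery

Kaplan–Meier estimation, the k-sample log-rank test and Cox proportional
hazards (Efron tie handling, Newton–Raphson) are delegated to `lifelines`;
monotone-likelihood failures are flagged non-converged with coefficients
capped at |β| ≤ 15. The package carries its own Efron partial-likelihood
evaluator, used as an independent brute-force oracle in tests and for
cross-validated deviance in the LASSO stage. Univariate prognostic
filtering fits each gene on z-scored expression (hazard ratios per SD) and
keeps Wald p < 0.05.

The score cutpoint is maximally selected: all score thresholds keeping
both groups ≥ 10% of the cohort are scanned for the largest absolute
standardized two-group log-rank statistic, and significance comes from
permuting the score–outcome pairing (default 1000 permutations). Note the
maximal statistic need not split near the median even under a perfectly
prognostic score; for exactly ordered data it peaks at an off-centre
split, which is expected behaviour of the statistic, not a defect.
Time-dependent ROC uses the IPCW cumulative-case/dynamic-control AUC from
`scikit-survival`. Rank-based group comparisons use the exact rank-sum
distribution when the combined n ≤ 10 without ties, the asymptotic
approximation otherwise.

## The CupScore

Given the prognostic pool (optionally sparsified by an L1-penalised Cox
stage: glmnet-style coordinate descent via `scikit-survival`, penalty
chosen by 10-fold Verweij–van Houwelingen cross-validated deviance with
the 1-SE rule), genes are z-scored on the training cohort and the first
two right singular axes w1, w2 of the standardised samples × genes array
are extracted. A sample's score is the sum of its projections on both
axes:

    score_s = Σ_i (w1_i + w2_i) · z_si.

This is the GGI-style reading of a two-component signature score; the
alternative reading (a sample-independent sum of loadings) carries no
per-sample information and is rejected. Axis signs are fixed
deterministically (largest-|loading| positive), and if the training scores
correlate negatively with mean regulator-panel expression both axes are
flipped together, so high score ⇔ high regulator expression by
construction. New cohorts are scored with the training μ, σ — no
re-standardisation — making the model portable, and the fitted model
serialises to JSON.

## Synthetic cohorts

The generator emulates the statistical skeleton the analysis assumes, with
every draw flowing from one seed (equal seeds ⇒ bit-identical cohorts):

* **Expression**: gene baselines ~ N(5, 2²) log2 units, residual noise
  σ = 1, n = 450 samples × 3000 genes, 2 batches with gene-level batch
  offsets ~ N(0, 0.5²).
* **Patterns**: 3 clusters in equal proportions. Each cluster
  over-expresses its own contiguous block of the 13-gene panel by +1.5 and
  under-expresses the rest by −1.5, plus a linspace(−0.5, 0.5)·shift
  offset that orders panel means A < B < C. The block design places the
  cluster centroids at balanced mutually negative correlations *after*
  both gene-centring and the per-profile centring implicit in the Pearson
  distance — the geometry the clustering stage actually sees. Constant
  (flat) shift patterns are avoided deliberately: they are invisible to a
  correlation distance.
* **DEGs**: 300 genes — 75 private to each cluster (up-regulated there
  only) plus a 75-gene graded block rising monotonically across A→B→C,
  effects ~ |N(0.8, 0.2²)|. Private blocks make pairwise discovery
  non-trivial but can never satisfy the all-pairs intersection; the graded
  block is the planted answer for the overlap rule, and its monotone
  association with the hazard ordering gives the score a recoverable
  prognostic axis.
* **Survival**: exponential with baseline hazard 1/600 per day (median
  ~14 months untreated baseline, a realistic GBM scale) and per-cluster
  log-hazards (0, 0.4, 0.9) for A/B/C; independent Uniform(0, H) censoring
  with H solved numerically so the expected censoring fraction equals the
  configured 30%. A Weibull shape parameter is exposed; 1 (exponential)
  is the default for closed-form recoverability.
* **Clinical**: age ~ N(60, 10²); IDH-mutant probability (0.30, 0.15,
  0.05) by cluster; molecular subtype tied to cluster; TMZ exposure
  Bernoulli(0.6).
* **Mutations/CNV**: per-gene Bernoulli mutation rates (default 1% per
  regulator) and independent ±1 CNV calls (default 10%/10% amp/del). A
  separate fixed worked fixture reproduces the published regulator
  mutation landscape exactly (390 samples, 9 panel-mutated, ATP7A most
  frequent, FDX1/LIAS/GCSH unmutated).

What the generator does **not** emulate: real GBM marginal distributions,
gene–gene correlation beyond the planted blocks, copy-number segments,
covariate-dependent censoring, or cohort-specific platform effects beyond
additive gene-level shifts. Passing tests therefore demonstrate that the
algorithms recover planted structure under the stated noise model, not
that the biological conclusions of any particular cohort reproduce.

## Numerical choices and degenerate inputs

* ssGSEA: rank weighting exponent α = 0.25; ties in the expression
  ranking break by gene id for determinism; sets intersecting the matrix
  in <2 genes are skipped; a set covering the whole universe is rejected
  (its out-of-set walk is undefined); normalised scores are per-set
  min–max across samples with the constant case mapping to 0.5. The
  immune/stromal composite scores are means of normalised ssGSEA scores
  over user-supplied signature collections — a signature-based stand-in
  for compartment deconvolution, recorded in the run manifest.
* Duplicate gene symbols at read time collapse to the row with the
  highest mean expression.
* Moderated-t hyperparameter estimation excludes zero-variance genes;
  a zero-variance, zero-difference gene reports t = 0, p = 1.
* Consensus entries for never-co-sampled pairs are 0; with ≥ 50 resamples
  at 80% subsampling the event is practically impossible.
* Fisher mutual-exclusivity reports an infinite sample odds ratio as inf
  with a flag rather than capping silently; direction comes from OR vs 1.
* TMB is reported as raw mutation count per sample; per-megabase needs a
  user-supplied capture size.
* All pipeline randomness (subsampling, CV folds, permutations) derives
  from one master seed via independent spawned streams; identical seeds
  reproduce every output bit-for-bit.

## Problem sizes used in the shipped checks

The packaged tests and the acceptance script run the default cohort
(n = 450, 3000 genes) with 200 consensus resamples and 200 cutpoint
permutations, calibration nulls of 3000 genes, and Cox recovery at
n = 500 — sizes at which every planted-recovery check is stable across
seeds while the whole suite stays fast.

## Known limitations

* The ssGSEA substitution does not reproduce proprietary deconvolution
  signature matrices; only signature-set scoring is supported.
* The LASSO stage can return the full pool (with a warning) when no
  penalty yields non-empty support; the pipeline then scores on the
  unsparsified pool.
* PAC-based k selection assumes over-splitting is less stable than the
  true partition; pathological data with genuinely nested structure at
  multiple scales may still require inspecting the reported PAC/delta-area
  series by eye, which is why both are returned.
* Batch correction without covariates will absorb biological signal that
  is perfectly confounded with batch; the generator assigns batches
  independently of cluster, real cohorts may not.
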