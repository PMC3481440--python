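# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind the package, and what the synthetic benchmark does
and does not establish about real data.

## The procedure and its assumptions

The pipeline looks for molecular subtypes with distinct progression-free
survival (PFS) under a *single, fixed* chemotherapy — the paclitaxel +
carboplatin doublet — on matched log2 expression, copy-number log2-ratio
and methylation beta-value matrices with clinical follow-up.  Its central
assumptions are:

* **Batch effects are location/scale.**  Expression values from batch *j*
  are assumed to differ from the study-wide distribution of each feature
  only by a shift and a scale; the correction
  `g* = M_i + (g − M_ij)·σ̂_i/σ̂_ij` (medians `M`, scale `σ̂`) removes
  exactly that.  Beta values are bounded in [0, 1] and mildly bimodal, so
  they are instead pushed through a two-piece linear map that fixes 0 and 1
  and sends the batch median onto the study-wide median.  Copy-number
  ratios are measured against co-hybridised normal DNA and are not
  corrected.
* **Treatment homogeneity beats sample size.**  Only stage III/IV samples
  whose paclitaxel *and* carboplatin records each start within 30 days of
  surgery and run ≥ 4 cycles are analysed; samples additionally exposed to
  any other drug before their failure (or censoring) day are quarantined
  into a held-out testing cohort rather than pooled.
* **Survival association is screened per feature, on discrete states.**
  Copy-number states use fixed cutoffs (gain > 0.4, loss < −0.5, the
  inclusive band between is normal); methylation states use per-feature
  empirical 0.25/0.75 quantiles (linear interpolation, computed on observed
  values, stored for later reuse on held-out cohorts).  A two-group
  log-rank test compares the altered against the reference group, only
  when both groups hold at least max(⌈0.15·n⌉, 13) samples, at α = 0.05.
* **Confounders are handled by refinement, not modelling.**  Rather than a
  multivariate survival model, the procedure removes candidate features
  whose tested groups differ in age (Wilcoxon rank-sum p < 0.05) or stage
  composition (Fisher exact p < 0.05); for methylation, features whose
  betas track age (|Spearman| > 0.5) or differ between stage III and IV.
  Features whose gene lacks a concordant ≥ 1.3× expression fold change
  (difference of group means on the log2 scale) are also dropped — copy
  number or methylation changes that do not touch transcription are not
  considered drivers.
* **Ternary scores denoise the data before clustering.**  Each retained
  feature contributes +1/0/−1 per sample (favourable/unknown/unfavourable,
  by the feature's log-rank survival direction; the state outside the
  tested contrast and missing values give 0).  The Jaccard mismatch
  distance over informative positions feeds complete-linkage clustering,
  cut at exactly two clusters; the lower-mean-score cluster is the
  poor-prognosis class (PPT).  A classification is only *proposed* — and
  only then carried into integration, held-out validation and
  differential expression — when the two clusters separate in PFS at
  log-rank p < 0.05.
* **Validation is by classification, not re-discovery.**  Held-out samples
  are discretised with the training cohort's features, cutoffs and
  directions (no re-estimation, no leakage) and labelled by a K = 3
  nearest-neighbour vote weighted by inverse Jaccard distance, with
  `max(#mismatch, 1)` in the numerator so identical profiles still get a
  finite weight; a tied vote (P_f = 0) is called poor.

No multiple-testing correction is applied anywhere — the scans use raw
p-value thresholds.  This is deliberate fidelity to the procedure and a
documented limitation: the expected number of false survivors of the scan
is α-level (verified by the null-cohort tests), and occasionally a false
feature survives the whole funnel and is "proposed" (its cluster split
inherits the scanned feature's significance).  Users who want control can
enable the optional Benjamini–Hochberg column in the differential-
expression output.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| cn gain / loss cutoffs | 0.4 / −0.5 | log2 ratio | standard array-CGH calling thresholds |
| beta quantiles | 0.25 / 0.75 | — | per-feature; a global cutoff would make "hypermethylated" vacuous for bimodal CpGs |
| scan α, confounder α | 0.05 | — | raw, uncorrected |
| minimum group size | max(⌈0.15·n⌉, 13) | samples | the two printed readings of the rule coincide at n = 85 |
| fold-change screen | 1.3× (selection), 1.5× (DE) | linear | inclusive boundary, 1e-12 tolerance |
| DE significance | 0.01 | — | Welch t-test by default (unequal group sizes); an equal-variance flag exists for sensitivity runs |
| K (neighbour count) | 3 | samples | weighted vote, ties to poor |
| scale estimator | sd (MAD optional) | — | MAD carries the 1.4826 consistency constant so both agree on normal data |

Batch-size guard: a warning is raised when any batch has fewer than 25
samples, where L/S scale estimates get unstable.

## The synthetic cohort

`simulate.SimConfig` defaults define the benchmark conditions at desk
scale: 240 samples → ~84 training / ~84 testing after the eligibility
funnel (vs 85/83 in a full-scale study), 13 processing batches, 2,000
genes, 1,000 CpGs.  Two planted poor-prognosis subtypes partition the
cohort with the good-prognosis rest: `cn_ppt` (20%) carries a contiguous
40-gene amplified segment (log2 ratio +0.8) with concordant +0.8 log2
expression shift; `meth_ppt` (30%) carries 60 hypomethylated CpGs
(beta −0.25) whose mapped genes are also up-shifted.  PFS is exponential
(Weibull shape exposed) with baseline median 396 days and the hazard of
*any* poor subtype multiplied by 3; independent uniform administrative
censoring is calibrated to a 16% censored fraction.  Ages (34–87), the
stage-IV fraction (0.165) and the subtype fractions echo the reported
cohort characteristics.  Batch effects are a per-batch location shift
(sd 0.3) and scale factor (U[0.7, 1.4]) on expression and a per-batch
median shift (±0.05) on betas — never on copy number.  Treatment
histories are generated so that configured fractions satisfy the
training rules, only the testing rules, or fail for rotating reasons
(stage, late start, few cycles, missing drug).

Confounding is injected only on decoy features: decoy copy-number genes
whose carriers are the oldest (or most stage-IV-enriched) quarter of the
cohort, and decoy CpGs whose betas track age or stage.  Age and stage are
*not* prognostic by default (knobs exist): making them globally prognostic
acts as frailty that dilutes the planted hazard ratio, and confining
confounding to designated features keeps the null configuration
exchangeable across subtypes.  Under the neutral default, decoys reach the
refinement stage only at α-level rates; the refinement filters are
therefore additionally exercised by directly constructed confounded
candidates in the test suite.

**What the benchmark does not emulate:** probe-level microarray signal,
genome structure/LD, correlated (rather than partitioned) subtypes,
informative censoring, and feature-feature correlation beyond the planted
blocks.  Passing tests show the machinery recovers the structure it
assumes; they are not evidence about discovery power on any real cohort.

**A property of the two-subtype model worth knowing:** because *both*
planted subtypes share the hazard ratio, each modality's scan tests its
altered group against a reference that contains the *other* subtype, which
dilutes the effective hazard ratio (to ≈ 1.75 for copy number at the
default fractions) and caps per-feature scan power at roughly 0.65 (CN) /
0.86 (methylation) with ~70 events.  Per-feature retention of planted
features on the default cohort is correspondingly below the ~95% one
would see for an isolated subtype; the funnel-retention property tests
therefore run on single-subtype cohorts, and the acceptance script
reports the retention observed on the default cohort.

## Numerical conventions

* Median of an even count is the mean of the central order statistics;
  consequently the beta-value piecewise map preserves batch medians
  *exactly* only for odd batch sizes (an even-count median can straddle
  the map's kink).  All statistics use observed entries only; missing
  entries stay missing through every transform.
* Degenerate cases: a zero within-batch scale pins that batch's values at
  the global median (flagged); a singleton batch passes through with a
  warning; a batch median of 0 or 1 disables the undefined branch of the
  beta map (flagged).  Wilcoxon on identical values returns p = 1; Fisher
  with a zero margin returns p = 1; Spearman on a constant vector is 0
  with a warning; a t-test with zero variance on both sides returns 1/0 by
  mean equality (flagged).  Log-rank with zero total variance returns
  p = 1 flagged; a feature whose log-rank direction is undefined (observed
  = expected) cannot be oriented and is dropped.
* Applying the expression correction twice is idempotent only up to the
  (small) gap between per-batch means and medians; the test suite bounds
  the second-pass movement at 5% of the first.
* Complete linkage uses a deterministic lexicographic tie-break on equal
  merge heights (smallest representative indices first), so runs are
  bit-reproducible; scipy's implementation is the cross-check on tie-free
  inputs and a from-scratch diameter recomputation is the oracle at n ≤ 8.
  Mutually uninformative sample pairs (no nonzero score in either) get
  distance 1 and are flagged.  KNN neighbour ties break by training-sample
  identifier order.
* A feature selected under both of its contrasts is scored by the contrast
  with the smaller log-rank p-value.  Fold-change and DE boundaries are
  inclusive with a 1e-12 tolerance on the log2 scale.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seed + config reproduces every
  matrix bit-for-bit.

## Test-suite design notes

Statistical correctness is checked against independent oracles: exhaustive
permutation of the log-rank statistic (n = 8, plain per-event-time
implementation), hypergeometric and rank-split enumeration for Fisher and
Wilcoxon, hand product-limit arithmetic for Kaplan–Meier, the
Welch–Satterthwaite formula evaluated by hand, and lifelines as an
external cross-check for the log-rank test.  Attained test sizes are
verified within [0.03, 0.07] over 1,000 exchangeable-null replicates per
test; the Fisher null uses 200-sample tables because the exact test's
discreteness dominates below that.  End-to-end recovery runs the full
pipeline over 50 seeded replicates of the default cohort and checks
aggregate truth-subtype recovery ≥ 80% and held-out log-rank significance
in ≥ 80% of replicates.  Problem sizes throughout (e.g. 500 × 200 × 8
batches for the correction invariants, 2,000 null features for scan
calibration) were chosen to match the stated benchmark conditions while
keeping the suite quick on one CPU.

## Known limitations

* Uncorrected multiplicity in every scan (inherited from the procedure).
* The two-cluster cut is fixed; a largest-gap cut exists as an option but
  is off by default, and no consensus/stability assessment is performed.
* The L/S model ignores batch-by-feature interactions beyond scale, and
  empirical-Bayes shrinkage (for small batches) is out of scope.
* Gene-ontology enrichment of the DE lists is out of scope; the ranked
  gene table is exportable to any external enrichment tool.
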