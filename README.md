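# chemoresponse

Confounder- and suppression-aware discovery of molecular subtypes with
distinct response to first-line paclitaxel/carboplatin chemotherapy in
ovarian serous carcinoma, from matched expression, copy-number and
methylation profiles with clinical follow-up.

Pooling heterogeneous treatments suppresses real survival associations, and
processing batches, patient age and tumour stage confound them.  This
package implements an integrated procedure that attacks both problems:

1. **Batch correction** — location/scale (L/S) adjustment of log2
   expression, `g* = M_i + (g − M_ij)·σ̂_i/σ̂_ij`, and a bounded
   piecewise-linear median alignment for methylation beta values
   (copy-number ratios, being comparative hybridisations, are left alone).
2. **Sample selection** — progression-free survival (PFS) is the interval
   from surgical resection to progression/recurrence/death, censored at
   last follow-up; eligible samples are stage III/IV with both drugs
   started ≤ 30 days after surgery and given ≥ 4 cycles.  Samples never
   given any other drug before failure form the *training* cohort; eligible
   samples with additional drugs are held out for *testing*.
3. **Semi-supervised feature screening** — per feature, survival of the
   altered group (copy-number gain > 0.4 / loss < −0.5; beta above the 0.75
   or below the 0.25 per-feature quantile) is contrasted against the
   reference group by a log-rank test, gated by a minimum group size of
   max(⌈0.15·n⌉, 13) and α = 0.05; candidates confounded by age (Wilcoxon,
   or |Spearman| > 0.5 vs age for betas) or stage (Fisher exact / Wilcoxon)
   are removed, and only features with a concordant ≥ 1.3× expression fold
   change survive.
4. **F-score clustering** — each selected feature maps samples onto ternary
   *F-scores* (+1 favourable / 0 unknown / −1 unfavourable by the log-rank
   survival direction); samples are clustered by the Jaccard mismatch
   distance `d(k,k′) = #(F_k ≠ F_k′) / #(F_k ≠ 0 ∨ F_k′ ≠ 0)` with complete
   linkage, cut into two clusters; the cluster enriched with unfavourable
   scores is the poor-prognosis class (PPT), proposed when the clusters'
   PFS differs at log-rank p < 0.05.  Copy-number- and methylation-derived
   PPT sets are unioned; everything else is the good-prognosis class (GPT).
5. **Weighted-KNN validation** — held-out samples are discretised with the
   *training* features, cutoffs and directions, and classified by the K = 3
   nearest training profiles voting with weights 1/d (`P_f > 0` ⇒ good,
   otherwise poor).
6. **Differential expression** — Welch t-test (p < 0.01) plus ≥ 1.5× fold
   change between each PPT class and the GPT group.

A synthetic-cohort generator (`chemoresponse.simulate`) reproduces the
statistical structure this analysis assumes — batch shifts, a planted
amplified segment with concordant up-regulation, a planted hypomethylated
CpG set, treatment histories, right-censored exponential PFS with a
hazard ratio between subtypes — with ground-truth labels, so every stage
is testable without any data download.

## Worked example

```python
from chemoresponse import PipelineConfig, run_all, summarize

result = run_all(PipelineConfig(seed=1))   # simulates the default cohort
print(summarize(result.report))
```

prints

```
chemoresponse v0.1.0 (seed 1)
samples: 240 total | 84 training | 84 testing | 72 excluded
  excluded[cycles]: 18
  excluded[missing_drug]: 18
  excluded[stage]: 18
  excluded[start_delay]: 18
features[copy_number]: scanned=2000 -> selected=23 -> after_confounders=19 -> after_foldchange=18 -> final=18
features[methylation]: scanned=1000 -> selected=144 -> after_confounders=132 -> after_foldchange=43 -> final=43
training clusters[copy_number]: PPT=12 GPT=72 log-rank p=0.0078
training clusters[methylation]: PPT=22 GPT=62 log-rank p=0.0155
training integrated: PPT=34 (overlap 0) GPT=50 log-rank p=0.00011 proposed=True
testing: PPT=50 (overlap 0) GPT=34 log-rank p=1.31e-07
differentially expressed genes[copy_number PPT vs GPT]: 44
differentially expressed genes[methylation PPT vs GPT]: 58
```

Reading this: of 240 simulated samples, 84 qualify as training and 84 as
testing.  The screening funnel keeps 18 copy-number features and 43 CpGs;
clustering their F-scores proposes a 34-sample poor-prognosis class with
clearly shorter PFS than the 50 good-prognosis samples (p ≈ 1e-4), the
weighted-KNN calls transfer the separation to the held-out cohort
(p ≈ 1e-7), and the final screen returns the candidate gene lists.

The same pipeline runs from the shell, on simulated or on-disk TSV data:

```sh
chemoresponse run-all --simulate --seed 1 --report report.json
chemoresponse simulate --seed 1 --out cohort/
chemoresponse select-samples --clinical cohort/clinical.tsv \
    --treatments cohort/treatments.tsv --out cohorts.tsv
```

Estimator classes (`LocationScaleBatchCorrector`,
`SurvivalFeatureDiscretizer`, `WeightedJaccardKNN`, …) follow the
scikit-learn fit/transform/predict protocol and compose with sklearn
tooling; the module-level functions are thin wrappers over them.

## Layout

```
src/chemoresponse/
  io.py         data model, TSV readers/writers, validation
  batch.py      L/S expression correction, bounded beta correction
  selection.py  PFS derivation and eligibility rules
  stats.py      log-rank (with direction), KM, rank/exact/t tests
  features.py   status discretisation, gated scan, refinements
  fscore.py     F-scores, Jaccard distance, complete linkage, integration
  knn.py        weighted-KNN model, JSON model serialisation
  diffexpr.py   fold-change + Welch t screen
  simulate.py   synthetic cohort generator with ground truth
  pipeline.py   end-to-end orchestration and run report
  cli.py        `chemoresponse` command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults,
numerical conventions and known limitations.
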