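"""Synthetic multi-omics cohorts with planted prognosis subtypes.

The generator emulates the statistical structure the analysis assumes, at
desk scale, with ground truth attached:

* two poor-prognosis subtypes -- ``cn_ppt`` carries a contiguous amplified
  copy-number segment with concordant expression up-regulation, ``meth_ppt``
  a hypomethylated CpG set (also with concordant expression change on the
  mapped genes); both have their progression hazard multiplied by a common
  hazard ratio.  Everyone else is ``gpt``;
* per-batch location/scale shifts on expression and per-batch median shifts
  on beta values (copy-number ratios carry no batch effect, matching how
  comparative-hybridisation arrays behave);
* age and stage are genuinely prognostic, and a set of decoy features is
  tied to age or stage only -- these acquire survival association purely
  through the confounder, giving the refinement filters true positives;
* right-censored progression-free survival from an exponential (optionally
  Weibull) model with independent uniform administrative censoring;
* treatment histories built so a configured fraction of samples satisfies
  the training rules, a fraction only the testing rules, and the rest fail
  eligibility for rotating reasons (stage, late start, too few cycles,
  missing drug).

Identical seed and config give a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, OmicsMatrix, write_clinical, write_matrix

OTHER_DRUGS = ("gemcitabine", "doxorubicin", "topotecan", "etoposide")


@dataclass
class SimConfig:
    """Data-generating parameters; defaults mirror the study at desk scale.

    Sizes: 240 samples of which ~35% satisfy the training rules and ~35%
    only the testing rules (~168 eligible, ~84/84, vs the study's 85/83);
    13 processing batches; 2,000 genes and 1,000 CpG sites.  Subtype
    fractions 0.20 / 0.30 echo the study's 18 and 30 poor-prognosis calls
    per 85 training samples.  Baseline median PFS 396 days, ~16% censoring,
    ages 34-87 and a stage-IV fraction of 0.165 match the reported cohort
    characteristics.
    """

    n_samples: int = 240
    n_genes: int = 2000
    n_cpg: int = 1000
    n_batches: int = 13
    batch_location_sd: float = 0.3          # log2 units
    batch_scale_range: tuple = (0.7, 1.4)
    beta_batch_median_shift: float = 0.05   # beta units
    frac_cn_ppt: float = 0.20
    frac_meth_ppt: float = 0.30
    planted_segment: tuple = ("1", 100, 40)  # chromosome, start index, length
    cn_gain_mean: float = 0.8               # log2 ratio
    expr_shift: float = 0.8                 # log2
    beta_hypo_shift: float = 0.25           # beta units
    n_planted_cpg: int = 60
    baseline_median_pfs: float = 396.0      # days
    ppt_hazard_ratio: float = 3.0
    censoring_rate: float = 0.16
    age_range: tuple = (34, 87)
    stage4_frac: float = 0.165
    n_decoy_confounded: int = 20
    missing_rate: float = 0.02
    seed: int = 0
    # cohort-role and nuisance structure
    frac_training: float = 0.35
    frac_testing: float = 0.35
    weibull_shape: float = 1.0              # 1 = exponential
    age_hazard_per_decade: float = 1.0
    stage4_hazard_ratio: float = 1.0
    cn_noise_sd: float = 0.25
    expr_noise_sd: float = 0.5
    beta_noise_sd: float = 0.06

    def validate(self) -> None:
        for name in ("frac_cn_ppt", "frac_meth_ppt", "censoring_rate",
                     "stage4_frac", "missing_rate", "frac_training",
                     "frac_testing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_cn_ppt + self.frac_meth_ppt > 1:
            raise ValueError("subtype fractions exceed 1")
        if self.frac_training + self.frac_testing > 1:
            raise ValueError("cohort-role fractions exceed 1")
        if self.ppt_hazard_ratio <= 0:
            raise ValueError("ppt_hazard_ratio must be positive")
        _, start, length = self.planted_segment
        if not (0 <= start and start + length <= self.n_genes):
            raise ValueError("planted segment does not fit inside n_genes")
        if self.n_planted_cpg > self.n_cpg:
            raise ValueError("n_planted_cpg exceeds n_cpg")
        for frac, label in ((self.frac_cn_ppt, "cn_ppt"),
                            (self.frac_meth_ppt, "meth_ppt")):
            # a zero fraction disables the subtype; a planted one needs >= 2
            if frac > 0 and round(frac * self.n_samples) < 2:
                raise ValueError(
                    f"planted subgroup {label} would have fewer than 2 samples")


@dataclass
class SyntheticCohort:
    """Generated matrices, clinical table, and the planted ground truth."""

    expression: OmicsMatrix
    copy_number: OmicsMatrix
    methylation: OmicsMatrix
    clinical: ClinicalTable
    truth_labels: pd.Series                  # sample -> {cn_ppt, meth_ppt, gpt}
    truth_features: dict = field(default_factory=dict)
    intended_roles: pd.Series | None = None  # sample -> {training, testing, excluded}

    @property
    def cpg_to_gene(self) -> dict:
        ann = self.methylation.annotations
        return dict(zip(ann.index, ann["gene_symbol"]))


def _censoring_window(t: np.ndarray, rate: float) -> float:
    """Window W of uniform administrative censoring C ~ U(0, W) such that
    the expected censored fraction mean(min(T/W, 1)) equals ``rate``."""

    def frac(w):
        return float(np.mean(np.minimum(t / w, 1.0))) - rate

    lo, hi = float(t.max()) * 1e-6, float(t.max()) * 1e6
    return brentq(frac, lo, hi, xtol=1e-6)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; same config and seed reproduce it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = np.array([f"S{i:04d}" for i in range(n)])
    gene_ids = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    cpg_ids = np.array([f"cg{i:05d}" for i in range(config.n_cpg)])

    # -- ground truth subtypes and cohort roles ---------------------------
    n_cn = round(config.frac_cn_ppt * n)
    n_meth = round(config.frac_meth_ppt * n)
    perm = rng.permutation(n)
    subtype = np.full(n, "gpt", dtype=object)
    subtype[perm[:n_cn]] = "cn_ppt"
    subtype[perm[n_cn:n_cn + n_meth]] = "meth_ppt"
    n_train = round(config.frac_training * n)
    n_test = round(config.frac_testing * n)
    perm2 = rng.permutation(n)
    role = np.full(n, "excluded", dtype=object)
    role[perm2[:n_train]] = "training"
    role[perm2[n_train:n_train + n_test]] = "testing"

    # -- clinical covariates ----------------------------------------------
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    stage = np.where(rng.random(n) < config.stage4_frac, "IV", "III").astype(object)
    batch = rng.integers(0, config.n_batches, n)
    excl_idx = np.nonzero(role == "excluded")[0]
    excl_mode = {s: m for m, s in zip(
        np.arange(len(excl_idx)) % 4, excl_idx)}
    for s, m in excl_mode.items():
        if m == 0:
            stage[s] = "other"

    # -- survival ----------------------------------------------------------
    is_ppt = subtype != "gpt"
    log_hr = (np.where(is_ppt, np.log(config.ppt_hazard_ratio), 0.0)
              + np.log(config.age_hazard_per_decade) * (ages - 60) / 10.0
              + np.where(stage == "IV", np.log(config.stage4_hazard_ratio), 0.0))
    shape = config.weibull_shape
    base_scale = config.baseline_median_pfs / np.log(2) ** (1.0 / shape)
    scale = base_scale / np.exp(log_hr) ** (1.0 / shape)
    t_true = scale * rng.weibull(shape, n)
    t_true = np.maximum(np.round(t_true), 2.0)
    if config.censoring_rate > 0:
        window = _censoring_window(t_true, config.censoring_rate)
        c = np.round(rng.uniform(0, window, n))
        c = np.maximum(c, 1.0)
        event = t_true <= c
        time = np.where(event, t_true, c)
    else:
        event = np.ones(n, bool)
        time = t_true

    # -- treatments ---------------------------------------------------------
    rows = []
    for k in range(n):
        sid = sample_ids[k]
        mode = excl_mode.get(k, None)
        start = int(rng.integers(1, 31))
        cycles = int(rng.integers(4, 9))
        if mode is None:  # training or testing: both drugs compliant
            rows.append((sid, "paclitaxel", start, cycles))
            rows.append((sid, "carboplatin", start, cycles))
            if role[k] == "testing":
                other = OTHER_DRUGS[int(rng.integers(0, len(OTHER_DRUGS)))]
                o_start = max(1, min(int(time[k]) - 1, 31 + int(rng.integers(0, 90))))
                rows.append((sid, other, o_start, int(rng.integers(2, 7))))
        elif mode == 0:  # stage exclusion; drugs themselves compliant
            rows.append((sid, "paclitaxel", start, cycles))
            rows.append((sid, "carboplatin", start, cycles))
        elif mode == 1:  # started too late
            late = 31 + int(rng.integers(0, 61))
            rows.append((sid, "paclitaxel", late, cycles))
            rows.append((sid, "carboplatin", late, cycles))
        elif mode == 2:  # too few cycles
            few = int(rng.integers(1, 4))
            rows.append((sid, "paclitaxel", start, few))
            rows.append((sid, "carboplatin", start, few))
        else:  # carboplatin never given
            rows.append((sid, "paclitaxel", start, cycles))
    treatments = pd.DataFrame(rows, columns=["sample_id", "drug", "start_day",
                                             "cycles"])

    clinical_df = pd.DataFrame({
        "age": ages,
        "stage": stage,
        "batch": [f"B{int(b):02d}" for b in batch],
        "event_day": np.where(event, time, np.nan),
        "event_observed": event,
        "last_followup_day": np.where(event, np.nan, time),
    }, index=pd.Index(sample_ids, name="sample_id"))

    # -- expression ---------------------------------------------------------
    chrom, seg_start, seg_len = config.planted_segment
    seg = np.arange(seg_start, seg_start + seg_len)
    mu_g = rng.normal(7.0, 1.5, config.n_genes)
    signal = rng.normal(0.0, config.expr_noise_sd, (n, config.n_genes))
    cn_carriers = subtype == "cn_ppt"
    meth_carriers = subtype == "meth_ppt"
    signal[np.ix_(cn_carriers, seg)] += config.expr_shift
    # CpG i maps to gene i (mod n_genes; several CpGs may share a gene);
    # planted CpGs sit first and their genes are disjoint from the default
    # planted segment
    cpg_gene_idx = np.arange(config.n_cpg) % config.n_genes
    planted_cpg = np.arange(config.n_planted_cpg)
    signal[np.ix_(meth_carriers, cpg_gene_idx[planted_cpg])] += config.expr_shift
    batch_loc = rng.normal(0.0, config.batch_location_sd, config.n_batches)
    batch_scale = rng.uniform(*config.batch_scale_range, config.n_batches)
    expr = (mu_g[None, :] + batch_loc[batch, None]
            + batch_scale[batch, None] * signal)

    # -- copy number --------------------------------------------------------
    cn = rng.normal(0.0, config.cn_noise_sd, (n, config.n_genes))
    cn[np.ix_(cn_carriers, seg)] += config.cn_gain_mean

    # -- methylation --------------------------------------------------------
    low = rng.random(config.n_cpg) < 0.5
    base_beta = np.where(low, rng.uniform(0.10, 0.35, config.n_cpg),
                         rng.uniform(0.60, 0.90, config.n_cpg))
    base_beta[planted_cpg] = rng.uniform(0.55, 0.80, config.n_planted_cpg)
    beta = base_beta[None, :] + rng.normal(0.0, config.beta_noise_sd,
                                           (n, config.n_cpg))
    beta[np.ix_(meth_carriers, planted_cpg)] -= config.beta_hypo_shift

    # -- decoy confounded features -----------------------------------------
    age_norm = (ages - ages.min()) / max(ages.max() - ages.min(), 1)
    n_decoy = config.n_decoy_confounded
    n_decoy_cn = n_decoy // 2
    n_decoy_meth = n_decoy - n_decoy_cn
    decoy_genes = np.arange(seg_start + seg_len,
                            seg_start + seg_len + n_decoy_cn)
    k_carriers = max(2, int(0.25 * n))
    for d, g in enumerate(decoy_genes):
        if d % 2 == 0:  # age-linked carriers
            score = 0.8 * age_norm + 0.2 * rng.random(n)
        else:           # stage-linked carriers
            score = 0.8 * (stage == "IV") + 0.2 * rng.random(n)
        carriers = np.argsort(-score, kind="mergesort")[:k_carriers]
        cn[carriers, g] += 0.8
    decoy_cpg = np.arange(config.n_planted_cpg,
                          config.n_planted_cpg + n_decoy_meth)
    for d, c0 in enumerate(decoy_cpg):
        if d % 2 == 0:  # beta tracks age
            beta[:, c0] = 0.75 - 0.45 * age_norm + rng.normal(0, 0.04, n)
        else:           # beta differs by stage
            beta[:, c0] = (0.45 + 0.25 * (stage == "IV")
                           + rng.normal(0, 0.04, n))
    beta = np.clip(beta, 0.0, 1.0)

    # -- missingness --------------------------------------------------------
    if config.missing_rate > 0:
        expr[rng.random(expr.shape) < config.missing_rate] = np.nan
        cn[rng.random(cn.shape) < config.missing_rate] = np.nan

    # -- assemble -----------------------------------------------------------
    gene_chrom = np.full(config.n_genes, "2", dtype=object)
    gene_chrom[seg] = chrom
    gene_ann = pd.DataFrame({
        "gene_symbol": gene_ids,
        "chromosome": gene_chrom,
        "position": np.arange(config.n_genes),
    }, index=pd.Index(gene_ids, name="feature_id"))
    cpg_ann = pd.DataFrame({
        "gene_symbol": gene_ids[cpg_gene_idx],
        "chromosome": gene_chrom[cpg_gene_idx],
        "position": np.arange(config.n_cpg),
        "cpg_id": cpg_ids,
    }, index=pd.Index(cpg_ids, name="feature_id"))

    def mat(values, ids, modality, ann):
        return OmicsMatrix(
            pd.DataFrame(values.T, index=pd.Index(ids, name="feature_id"),
                         columns=sample_ids),
            modality, ann)

    cohort = SyntheticCohort(
        expression=mat(expr, gene_ids, "expression", gene_ann),
        copy_number=mat(cn, gene_ids, "copy_number", gene_ann),
        methylation=mat(beta, cpg_ids, "methylation", cpg_ann),
        clinical=ClinicalTable(clinical_df, treatments),
        truth_labels=pd.Series(subtype, index=sample_ids, name="subtype"),
        truth_features={
            "cn_genes": list(gene_ids[seg]),
            "cpg_sites": list(cpg_ids[planted_cpg]),
            "decoy_genes": list(gene_ids[decoy_genes]),
            "decoy_cpgs": list(cpg_ids[decoy_cpg]),
        },
        intended_roles=pd.Series(role, index=sample_ids, name="role"),
    )
    return cohort


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as the pipeline's TSV file set; returns the paths."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": d / "expression.tsv",
        "copy_number": d / "copy_number.tsv",
        "methylation": d / "methylation.tsv",
        "clinical": d / "clinical.tsv",
        "treatments": d / "treatments.tsv",
        "truth_labels": d / "truth_labels.tsv",
    }
    write_matrix(cohort.expression, paths["expression"])
    write_matrix(cohort.copy_number, paths["copy_number"])
    write_matrix(cohort.methylation, paths["methylation"])
    write_clinical(cohort.clinical, paths["clinical"], paths["treatments"])
    truth = cohort.truth_labels.rename_axis("sample_id").reset_index()
    truth.to_csv(paths["truth_labels"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    from .io import read_clinical, read_matrix

    d = Path(directory)
    expression = read_matrix(d / "expression.tsv", "expression",
                             d / "features_expression.tsv")
    copy_number = read_matrix(d / "copy_number.tsv", "copy_number",
                              d / "features_copy_number.tsv")
    methylation = read_matrix(d / "methylation.tsv", "methylation",
                              d / "features_methylation.tsv")
    clinical = read_clinical(d / "clinical.tsv", d / "treatments.tsv")
    truth = pd.read_csv(d / "truth_labels.tsv", sep="\t",
                        index_col="sample_id")["subtype"]
    return SyntheticCohort(expression, copy_number, methylation, clinical,
                           truth)
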