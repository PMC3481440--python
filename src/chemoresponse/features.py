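"""Survival-driven feature screening with confounder and fold-change refinement.

Copy-number log2 ratios are discretised into gain (> 0.4), normal
([-0.5, 0.4]) and loss (< -0.5); batch-corrected beta values into
hypermethylated (> per-feature 0.75 quantile), mid and hypomethylated
(< 0.25 quantile).  A per-feature log-rank scan then contrasts the survival
of the altered group against the reference group (gain-vs-normal and
loss-vs-normal for copy number; hyper-vs-rest and hypo-vs-rest for
methylation), gated by a minimum group size of max(ceil(0.15 n), 13).

Candidates are refined in two passes: (1) confounder screening drops
features whose tested groups differ in age (Wilcoxon) or in stage III/IV
composition (Fisher) -- for methylation, features whose betas track age
(|Spearman| > 0.5) or differ between stage III and IV; (2) concordance
screening keeps only features whose gene shows an expression fold change of
at least 1.3x between the tested groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

# status codes shared by both modalities (int8 matrices)
GAIN, NORMAL, LOSS = 1, 0, -1
HYPER, MID, HYPO = 1, 0, -1
MISSING = -128

CN_CONTRASTS = ("gain_vs_normal", "loss_vs_normal")
METH_CONTRASTS = ("hyper_vs_rest", "hypo_vs_rest")

# group-1 status / group-2 statuses per contrast
_CONTRAST_GROUPS = {
    "gain_vs_normal": (GAIN, (NORMAL,)),
    "loss_vs_normal": (LOSS, (NORMAL,)),
    "hyper_vs_rest": (HYPER, (MID, HYPO)),
    "hypo_vs_rest": (HYPO, (HYPER, MID)),
}


@dataclass
class Thresholds:
    """Cutoffs of the screening funnel (printed values of the procedure)."""

    cn_gain: float = 0.4
    cn_loss: float = -0.5
    meth_hi_quantile: float = 0.75
    meth_lo_quantile: float = 0.25
    scan_alpha: float = 0.05
    min_group_frac: float = 0.15
    min_group_floor: int = 13
    confounder_alpha: float = 0.05
    age_spearman_cut: float = 0.5
    fc_cut: float = 1.3

    def __post_init__(self):
        if not self.cn_loss < self.cn_gain:
            raise ValueError("cn_loss must be below cn_gain")
        if not 0 < self.meth_lo_quantile < self.meth_hi_quantile < 1:
            raise ValueError("need 0 < lo quantile < hi quantile < 1")
        if not self.fc_cut > 1:
            raise ValueError("fc_cut must exceed 1")


@dataclass
class FeatureTest:
    """One feature's survival contrast with tested-group bookkeeping.

    ``group1_ids`` is the altered group (gain/loss/hyper/hypo) and
    ``group2_ids`` the reference; ``longer`` records which of the two had
    fewer observed than expected events in the log-rank test.
    """

    feature_id: str
    modality: str
    contrast: str
    p_value: float
    longer: str                      # "group1" or "group2"
    group1_ids: list
    group2_ids: list
    flags: set = field(default_factory=set)


def min_group_size(n: int, frac: float = 0.15, floor: int = 13) -> int:
    """Smallest admissible log-rank group: max(ceil(frac * n), floor)."""
    return max(math.ceil(frac * n), floor)


def categorize_cn(values: pd.DataFrame, thr: Thresholds | None = None) -> pd.DataFrame:
    """Discretise copy-number log2 ratios (samples x features) into statuses.

    Boundaries are inclusive for the normal band: gain strictly above
    ``cn_gain``, loss strictly below ``cn_loss``.
    """
    thr = thr or Thresholds()
    v = values.to_numpy(float)
    out = np.full(v.shape, NORMAL, dtype=np.int8)
    out[v > thr.cn_gain] = GAIN
    out[v < thr.cn_loss] = LOSS
    out[np.isnan(v)] = MISSING
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def categorize_meth(values: pd.DataFrame, thr: Thresholds | None = None,
                    cutoffs: pd.DataFrame | None = None):
    """Discretise beta values (samples x features) by per-feature quantiles.

    Quantiles use linear interpolation over observed values.  Passing
    ``cutoffs`` (columns ``lo`` and ``hi``, indexed by feature) reuses
    previously stored cutoffs -- this is how held-out cohorts are
    discretised with training-derived criteria.  Returns
    ``(status, cutoffs)``.
    """
    thr = thr or Thresholds()
    v = values.to_numpy(float)
    if cutoffs is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanquantile(v, thr.meth_lo_quantile, axis=0)
            hi = np.nanquantile(v, thr.meth_hi_quantile, axis=0)
        cutoffs = pd.DataFrame({"lo": lo, "hi": hi}, index=values.columns)
    else:
        cutoffs = cutoffs.reindex(values.columns)
        lo = cutoffs["lo"].to_numpy(float)
        hi = cutoffs["hi"].to_numpy(float)
    out = np.full(v.shape, MID, dtype=np.int8)
    out[v > hi[None, :]] = HYPER
    out[v < lo[None, :]] = HYPO
    out[np.isnan(v) | np.isnan(lo)[None, :].repeat(v.shape[0], 0)] = MISSING
    status = pd.DataFrame(out, index=values.index, columns=values.columns)
    return status, cutoffs


def scan_features(status: pd.DataFrame, pfs: pd.DataFrame, modality: str,
                  thr: Thresholds | None = None,
                  contrasts=None) -> list[FeatureTest]:
    """Log-rank scan of every feature/contrast passing the size gate.

    ``status`` is samples x features (int8 codes); ``pfs`` a DataFrame with
    ``time``/``event`` aligned on the same samples.  Only contrasts where
    both groups reach the minimum size are tested, and only tests with
    p < ``scan_alpha`` are returned.
    """
    thr = thr or Thresholds()
    if contrasts is None:
        contrasts = CN_CONTRASTS if modality == "copy_number" else METH_CONTRASTS
    pfs = pfs.loc[status.index]
    time = pfs["time"].to_numpy(float)
    event = pfs["event"].to_numpy(bool)
    n = status.shape[0]
    gate = min_group_size(n, thr.min_group_frac, thr.min_group_floor)
    codes = status.to_numpy()
    samples = status.index.to_numpy()
    results: list[FeatureTest] = []
    for contrast in contrasts:
        g1_code, g2_codes = _CONTRAST_GROUPS[contrast]
        in1 = (codes == g1_code).T                     # F x S
        in2 = np.isin(codes, g2_codes).T
        n1 = in1.sum(axis=1)
        n2 = in2.sum(axis=1)
        ok = (n1 >= gate) & (n2 >= gate)
        if not ok.any():
            continue
        include = in1[ok] | in2[ok]
        chi2, p, o1, e1 = stats.logrank_scan(time, event, in1[ok], include)
        feat_idx = np.nonzero(ok)[0]
        for row, fi in enumerate(feat_idx):
            if p[row] >= thr.scan_alpha:
                continue
            longer = "group1" if o1[row] < e1[row] else "group2"
            if np.isclose(o1[row], e1[row]):
                continue  # no direction; cannot orient scores
            results.append(FeatureTest(
                feature_id=status.columns[fi],
                modality=modality,
                contrast=contrast,
                p_value=float(p[row]),
                longer=longer,
                group1_ids=list(samples[in1[fi]]),
                group2_ids=list(samples[in2[fi]]),
            ))
    return results


def refine_confounders(tests: list[FeatureTest], clinical, modality: str,
                       values: pd.DataFrame | None = None,
                       thr: Thresholds | None = None):
    """Drop tests confounded by age or tumour stage.

    Copy number: Wilcoxon on the ages of the two tested groups, and Fisher
    on the group x stage (III/IV) 2x2 table.  Methylation: |Spearman| of the
    feature's betas against age, and Wilcoxon of betas between stage III and
    stage IV samples (``values`` must carry the beta matrix, samples x
    features).  Returns ``(kept, all_tests)`` where dropped tests stay in
    ``all_tests`` with flags set.
    """
    thr = thr or Thresholds()
    samples = clinical.samples
    kept = []
    for t in tests:
        if modality == "copy_number":
            a1 = samples.loc[t.group1_ids, "age"].to_numpy(float)
            a2 = samples.loc[t.group2_ids, "age"].to_numpy(float)
            if stats.wilcoxon_ranksum(a1, a2) < thr.confounder_alpha:
                t.flags.add("age_confounded")
            s1 = samples.loc[t.group1_ids, "stage"]
            s2 = samples.loc[t.group2_ids, "stage"]
            table = [[int((s1 == "III").sum()), int((s1 == "IV").sum())],
                     [int((s2 == "III").sum()), int((s2 == "IV").sum())]]
            if stats.fisher_exact_2x2(table) < thr.confounder_alpha:
                t.flags.add("stage_confounded")
        else:
            if values is None:
                raise ValueError("methylation refinement needs beta values")
            beta = values[t.feature_id]
            ages = samples.loc[beta.index, "age"].to_numpy(float)
            rho = stats.spearman(beta.to_numpy(float), ages)
            if abs(rho) > thr.age_spearman_cut:
                t.flags.add("age_confounded")
            st = samples.loc[beta.index, "stage"]
            b3 = beta[(st == "III").to_numpy()].dropna().to_numpy(float)
            b4 = beta[(st == "IV").to_numpy()].dropna().to_numpy(float)
            if len(b3) and len(b4) and \
                    stats.wilcoxon_ranksum(b3, b4) < thr.confounder_alpha:
                t.flags.add("stage_confounded")
        if not t.flags & {"age_confounded", "stage_confounded"}:
            kept.append(t)
    return kept, tests


def refine_foldchange(tests: list[FeatureTest], expression: pd.DataFrame,
                      feature_to_gene: dict | None = None,
                      thr: Thresholds | None = None):
    """Keep tests whose gene shows >= ``fc_cut`` expression fold change.

    ``expression`` is batch-corrected log2 values, samples x genes.  The
    fold change between the tested groups is the difference of group means
    on the log2 scale (ratio of geometric means); the boundary is inclusive
    up to a 1e-12 tolerance.  Features with no mapped gene in the expression
    matrix are dropped and flagged ``no_gene``.
    """
    thr = thr or Thresholds()
    cut = math.log2(thr.fc_cut) - 1e-12
    kept = []
    for t in tests:
        gene = t.feature_id if feature_to_gene is None else \
            feature_to_gene.get(t.feature_id)
        if gene is None or gene not in expression.columns:
            t.flags.add("no_gene")
            continue
        col = expression[gene]
        m1 = col.loc[[s for s in t.group1_ids if s in col.index]].mean()
        m2 = col.loc[[s for s in t.group2_ids if s in col.index]].mean()
        if abs(m1 - m2) >= cut:
            kept.append(t)
        else:
            t.flags.add("fc_failed")
    return kept, tests
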