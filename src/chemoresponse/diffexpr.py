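"""Differential expression between a poor-prognosis class and the good group.

Per gene, a Welch t-test on log2 expression plus a linear fold change
``2 ** (mean_a - mean_b)``; a gene *passes* when the fold change is at least
1.5x in either direction (inclusive boundary) and p < 0.01.  The two
poor-prognosis classifications (copy-number-derived and
methylation-derived) are each compared against the common good-prognosis
group separately -- their union is never pooled into one test.  No false
discovery rate correction is applied by default; an optional
Benjamini-Hochberg column can be requested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


def differential_expression(expression: pd.DataFrame, group_a, group_b,
                            fc_cut: float = 1.5, alpha: float = 0.01,
                            equal_var: bool = False,
                            add_bh: bool = False) -> pd.DataFrame:
    """Welch t-test + fold-change screen, sorted by p-value.

    Parameters
    ----------
    expression : pandas.DataFrame
        Batch-corrected log2 expression, samples x genes.
    group_a, group_b : sample id lists (disjoint, each with >= 2 samples).
    fc_cut, alpha : pass thresholds (fold change inclusive, p strict).
    add_bh : add a Benjamini-Hochberg adjusted p column.

    Returns a DataFrame indexed by gene with ``mean_a``, ``mean_b``,
    ``fold_change`` (linear), ``p_value`` and ``passes``.  Genes missing in
    more than half of either group are excluded; their count is in
    ``result.attrs["n_excluded"]``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = expression.loc[group_a].to_numpy(float)
    xb = expression.loc[group_b].to_numpy(float)
    ok_a = (~np.isnan(xa)).sum(axis=0) >= 0.5 * len(group_a)
    ok_b = (~np.isnan(xb)).sum(axis=0) >= 0.5 * len(group_b)
    enough = ((~np.isnan(xa)).sum(axis=0) >= 2) & \
             ((~np.isnan(xb)).sum(axis=0) >= 2)
    keep = ok_a & ok_b & enough
    n_excluded = int((~keep).sum())
    xa, xb = xa[:, keep], xb[:, keep]
    genes = expression.columns[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(xa, axis=0)
        mb = np.nanmean(xb, axis=0)
        res = sps.ttest_ind(xa, xb, equal_var=equal_var, nan_policy="omit",
                            axis=0)
        p = np.asarray(res.pvalue, float)
    # degenerate genes (zero variance in both groups): p undefined by t
    degenerate = np.isnan(p)
    p[degenerate & np.isclose(ma, mb)] = 1.0
    p[degenerate & ~np.isclose(ma, mb)] = 0.0
    fc = 2.0 ** (ma - mb)
    log_cut = np.log2(fc_cut) - 1e-12
    passes = (np.abs(ma - mb) >= log_cut) & (p < alpha)
    out = pd.DataFrame({
        "mean_a": ma, "mean_b": mb, "fold_change": fc,
        "p_value": p, "passes": passes,
    }, index=genes)
    if add_bh:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values("p_value", kind="mergesort")
    out.attrs["n_excluded"] = n_excluded
    return out
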