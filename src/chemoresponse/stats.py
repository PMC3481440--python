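"""Statistical primitives for the survival-driven feature scans.

The two-group log-rank test is implemented here (vectorised across features)
because the discretisation step needs per-group observed/expected event
counts to orient each feature's survival direction.  The remaining tests are
thin wrappers over ``scipy.stats`` / ``lifelines`` that pin down the edge-case
conventions the pipeline relies on (zero margins, constant vectors, ties).

No multiple-testing correction is applied anywhere: the procedure's scans use
raw p-value thresholds throughout, which is a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class LogRankResult:
    """Two-group log-rank outcome with a survival direction.

    ``longer`` names the group ("a" or "b") whose observed event count falls
    below its expectation under the null -- i.e. the longer-survival group.
    It is ``None`` when observed equals expected (no direction).
    """

    chi_square: float
    p_value: float
    longer: str | None
    observed: tuple[float, float]
    expected: tuple[float, float]
    degenerate: bool = False


def _as_time_event(outcomes) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(outcomes, pd.DataFrame):
        return (outcomes["time"].to_numpy(float),
                outcomes["event"].to_numpy(bool))
    arr = np.asarray(outcomes, dtype=float)
    return arr[:, 0].astype(float), arr[:, 1].astype(bool)


def logrank_scan(time, event, in_a, include):
    """Vectorised two-group log-rank tests sharing one set of outcomes.

    Parameters
    ----------
    time, event : arrays of shape (S,)
        Follow-up time in days and event indicator per sample.
    in_a : bool array (F, S)
        Membership of group A per feature.
    include : bool array (F, S)
        Samples taking part in the comparison (group A union group B).

    Returns
    -------
    chi2, p, o_a, e_a : arrays of shape (F,)
        Chi-square statistics (1 df), p-values, and group-A observed and
        expected event counts.  Features with zero log-rank variance get
        ``chi2 = 0`` and ``p = 1``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    in_a = np.atleast_2d(np.asarray(in_a, bool))
    include = np.atleast_2d(np.asarray(include, bool))
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    A = (in_a & include)[:, order]
    I = include[:, order]
    _, first = np.unique(t, return_index=True)

    # at-risk counts at each distinct time = suffix sums of membership
    def suffix_at(mask):
        c = np.cumsum(mask[:, ::-1].astype(np.int64), axis=1)[:, ::-1]
        return c[:, first]

    n_at = suffix_at(I).astype(float)
    na_at = suffix_at(A).astype(float)
    d = np.add.reduceat((I & e).astype(np.int64), first, axis=1).astype(float)
    da = np.add.reduceat((A & e).astype(np.int64), first, axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_at > 0, na_at / np.where(n_at > 0, n_at, 1.0), 0.0)
        e_a_t = d * frac
        v_t = d * frac * (1.0 - frac) * (n_at - d) / np.maximum(n_at - 1.0, 1.0)
    o_a = da.sum(axis=1)
    e_a = e_a_t.sum(axis=1)
    v = v_t.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(v > 0, (o_a - e_a) ** 2 / np.where(v > 0, v, 1.0), 0.0)
    p = sps.chi2.sf(chi2, df=1)
    p = np.where(v > 0, p, 1.0)
    return chi2, p, o_a, e_a


def logrank(group_a, group_b) -> LogRankResult:
    """Two-group log-rank test with the standard tie-corrected variance.

    Each argument is a DataFrame with ``time`` and ``event`` columns (or an
    (n, 2) array).  Requires both groups non-empty and at least one event
    overall.
    """
    ta, ea = _as_time_event(group_a)
    tb, eb = _as_time_event(group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("log-rank requires both groups non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank undefined with zero events")
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    in_a = np.zeros(len(time), bool)
    in_a[: len(ta)] = True
    include = np.ones(len(time), bool)
    chi2, p, o_a, e_a = logrank_scan(time, event, in_a[None, :], include[None, :])
    chi2, p, o_a, e_a = chi2[0], p[0], o_a[0], e_a[0]
    o_b = float(event.sum() - o_a)
    e_b = float(event.sum() - e_a)
    if np.isclose(o_a, e_a):
        longer = None
    else:
        longer = "a" if o_a < e_a else "b"
    degenerate = bool(chi2 == 0 and p == 1.0 and not np.isclose(o_a, e_a))
    return LogRankResult(float(chi2), float(p), longer,
                         (float(o_a), o_b), (float(e_a), e_b), degenerate)


def km_curve(outcomes) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with columns ``time``, ``survival`` and ``at_risk``
    (right-continuous step function starting at S(0) = 1).
    """
    from lifelines import KaplanMeierFitter

    t, e = _as_time_event(outcomes)
    if len(t) == 0:
        raise ValueError("km_curve requires at least one outcome")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index)
    return pd.DataFrame({
        "time": table.index.to_numpy(float),
        "survival": surv.to_numpy(float),
        "at_risk": table["at_risk"].to_numpy(int),
    }).reset_index(drop=True)


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both sides have <= 25 untied observations,
    otherwise the tie-corrected normal approximation.  Returns 1.0 when all
    values are identical.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("wilcoxon_ranksum requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(x), len(y)) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities no larger than the observed table's.
    A zero row or column margin makes the test vacuous: p = 1.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("fisher_exact_2x2 needs a nonnegative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(tab, alternative="two-sided")[1])


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks), missing pairs removed.

    A constant vector leaves the correlation undefined; it is reported as 0
    with a warning so downstream refinement treats it as uninformative.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("spearman requires >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("spearman: constant vector, correlation undefined -> 0")
        return 0.0
    return float(sps.spearmanr(x, y).statistic)


def two_sample_t(x, y, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    Zero variance on both sides is degenerate: p = 1 if the means agree,
    else 0 (flagged by warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("two_sample_t requires >= 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        warnings.warn("two_sample_t: zero variance in both groups")
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)
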