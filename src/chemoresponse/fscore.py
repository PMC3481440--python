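"""F-score discretisation, Jaccard distances and the semi-supervised clustering.

Each selected feature maps every sample onto a ternary *F-score*:
+1 (favourable) when the sample's status group was the longer-survival side
of the feature's log-rank contrast, -1 (unfavourable) for the shorter side,
and 0 (unknown) for the status left out of the contrast or missing values.
Samples are then compared by a Jaccard-style mismatch distance

    d(k, k') = #(F_k != F_k') / #(F_k != 0 or F_k' != 0)

and grouped by agglomerative complete-linkage clustering cut into two
clusters; the cluster enriched with unfavourable scores (lower mean F-score)
is labelled the poor-prognosis cluster (PPT), the other good-prognosis
(GPT).  A classification is only *proposed* when the two clusters separate
in progression-free survival at log-rank p < 0.05.

Complete linkage is computed with a deterministic lexicographic tie-break on
equal merge heights so repeated runs agree bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import stats
from .features import (_CONTRAST_GROUPS, Thresholds, FeatureTest,
                       categorize_cn, categorize_meth, refine_confounders,
                       refine_foldchange, scan_features)


@dataclass
class FScoreMatrix:
    """Ternary scores (samples x selected features) plus provenance."""

    scores: pd.DataFrame                 # int8 values in {-1, 0, +1}
    provenance: pd.DataFrame             # per feature: contrast, p_value, longer

    @property
    def sample_ids(self):
        return list(self.scores.index)

    @property
    def feature_ids(self):
        return list(self.scores.columns)


def dedupe_tests(tests: list[FeatureTest]) -> list[FeatureTest]:
    """Keep one test per feature: the contrast with the smaller p-value."""
    best: dict[str, FeatureTest] = {}
    for t in tests:
        cur = best.get(t.feature_id)
        if cur is None or t.p_value < cur.p_value:
            best[t.feature_id] = t
    return list(best.values())


def assign_fscores(tests: list[FeatureTest], status: pd.DataFrame) -> FScoreMatrix:
    """Discretise samples into F-scores for each selected feature.

    ``status`` is samples x features (int8 codes).  For each feature the two
    statuses of the winning contrast receive +/-1 by survival direction; the
    excluded status and missing values receive 0.
    """
    tests = dedupe_tests(tests)
    n = status.shape[0]
    cols = {}
    prov = []
    for t in tests:
        if t.longer is None:
            warnings.warn(f"feature {t.feature_id}: undefined direction, dropped")
            continue
        g1_code, g2_codes = _CONTRAST_GROUPS[t.contrast]
        col = status[t.feature_id].to_numpy()
        s = np.zeros(n, dtype=np.int8)
        in1 = col == g1_code
        in2 = np.isin(col, g2_codes)
        if t.longer == "group1":
            s[in1] = 1
            s[in2] = -1
        else:
            s[in1] = -1
            s[in2] = 1
        cols[t.feature_id] = s
        prov.append((t.feature_id, t.contrast, t.p_value, t.longer))
    scores = pd.DataFrame(cols, index=status.index, dtype=np.int8)
    provenance = pd.DataFrame(
        prov, columns=["feature_id", "contrast", "p_value", "longer"]
    ).set_index("feature_id")
    return FScoreMatrix(scores, provenance)


def _mismatch_union(A: np.ndarray, B: np.ndarray):
    """Pairwise mismatch and informative-union counts between score rows."""
    eq = np.zeros((A.shape[0], B.shape[0]), dtype=np.int64)
    for v in (-1, 0, 1):
        av = (A == v).astype(np.int64)
        bv = (B == v).astype(np.int64)
        eq += av @ bv.T
    mismatch = A.shape[1] - eq
    anz = (A != 0).astype(np.int64)
    bnz = (B != 0).astype(np.int64)
    union = anz.sum(1)[:, None] + bnz.sum(1)[None, :] - anz @ bnz.T
    return mismatch, union


def jaccard_distance(fscores) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-by-sample mismatch distance over informative positions.

    Pairs with no informative position in either sample get distance 1 and
    are flagged.  Returns ``(distance DataFrame, flagged boolean matrix)``.
    """
    scores = fscores.scores if isinstance(fscores, FScoreMatrix) else fscores
    if scores.shape[0] < 2:
        raise ValueError("need at least two samples")
    A = scores.to_numpy(np.int8)
    mismatch, union = _mismatch_union(A, A)
    flagged = union == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(flagged, 1.0, mismatch / np.where(flagged, 1, union))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(flagged, False)
    return pd.DataFrame(d, index=scores.index, columns=scores.index), flagged


def complete_linkage(D: np.ndarray, n_clusters: int = 1):
    """Agglomerative complete linkage with deterministic tie-breaking.

    On equal merge heights the pair with the lexicographically smallest
    (representative) member indices merges first.  Returns
    ``(labels, trace)`` where ``labels`` assigns each sample the cluster it
    belongs to when exactly ``n_clusters`` clusters remain (0-based,
    ordered by smallest member index) and ``trace`` lists every merge as
    ``(rep_i, rep_j, height, new_size)`` down to a single cluster.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    dist = D.copy()
    np.fill_diagonal(dist, np.inf)
    active = np.ones(n, bool)
    members = {i: [i] for i in range(n)}
    trace = []
    labels = None

    def snapshot():
        reps = sorted(i for i in range(n) if active[i])
        lab = np.empty(n, int)
        for c, r in enumerate(reps):
            lab[members[r]] = c
        return lab

    remaining = n
    while remaining > 1:
        if remaining == n_clusters:
            labels = snapshot()
        masked = np.where(active[:, None] & active[None, :], dist, np.inf)
        m = masked.min()
        idx = np.argwhere(masked == m)
        idx = idx[idx[:, 0] < idx[:, 1]]
        i, j = idx[np.lexsort((idx[:, 1], idx[:, 0]))[0]]
        members[i].extend(members[j])
        active[j] = False
        newd = np.maximum(dist[i], dist[j])
        dist[i] = newd
        dist[:, i] = newd
        dist[i, i] = np.inf
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        trace.append((int(i), int(j), float(m), len(members[i])))
        remaining -= 1
    if labels is None:  # n_clusters == n (or n == 1)
        labels = snapshot() if remaining == n_clusters else np.zeros(n, int)
    return labels, trace


@dataclass
class ClusterResult:
    """Two-cluster partition with PPT/GPT labelling and its survival check."""

    assignment: pd.Series        # sample -> cluster index
    ppt_ids: list
    gpt_ids: list
    logrank_p: float
    proposed: bool
    merge_trace: list
    flags: set = field(default_factory=set)


def cluster_samples(fscores: FScoreMatrix, pfs: pd.DataFrame,
                    distances: pd.DataFrame | None = None,
                    alpha: float = 0.05) -> ClusterResult:
    """Complete-linkage clustering of F-score profiles into PPT and GPT.

    The tree is cut into exactly two clusters; the cluster with the lower
    mean F-score is the poor-prognosis (PPT) side.  The classification is
    flagged ``proposed`` only when the clusters' progression-free survival
    differs at log-rank p < ``alpha``.
    """
    flags = set()
    if distances is None:
        distances, flagged = jaccard_distance(fscores)
        if flagged.any():
            flags.add("uninformative_pairs")
    labels, trace = complete_linkage(distances.to_numpy(), n_clusters=2)
    samples = fscores.scores.index
    assignment = pd.Series(labels, index=samples, name="cluster")
    means = [fscores.scores.to_numpy(float)[labels == c].mean()
             for c in (0, 1)]
    if np.isclose(means[0], means[1]):
        flags.add("degenerate_no_enrichment")
        ppt_c = 1
    else:
        ppt_c = int(np.argmin(means))
    ppt_ids = list(samples[labels == ppt_c])
    gpt_ids = list(samples[labels != ppt_c])
    if min(len(ppt_ids), len(gpt_ids)) <= 1:
        flags.add("singleton_cluster")
    pfs = pfs.loc[samples]
    try:
        lr = stats.logrank(pfs.loc[ppt_ids], pfs.loc[gpt_ids])
        p = lr.p_value
    except ValueError:
        flags.add("logrank_undefined")
        p = 1.0
    proposed = bool(p < alpha and "degenerate_no_enrichment" not in flags)
    return ClusterResult(assignment, ppt_ids, gpt_ids, float(p), proposed,
                         trace, flags)


@dataclass
class IntegratedClassification:
    """Union of modality-level PPT calls against the common GPT complement."""

    ppt_ids: list
    gpt_ids: list
    logrank_p: float
    proposed: bool


def integrate_classifications(results, pfs: pd.DataFrame,
                              alpha: float = 0.05) -> IntegratedClassification:
    """Combine per-modality cluster results: final PPT = union of PPT sets.

    ``results`` is an iterable of :class:`ClusterResult` over the same
    sample universe; samples in no PPT set form the GPT group.
    """
    results = [r for r in results if r is not None]
    if not results:
        raise ValueError("nothing to integrate")
    universe = sorted(set().union(*[set(r.assignment.index) for r in results]))
    ppt = sorted(set().union(*[set(r.ppt_ids) for r in results]))
    gpt = sorted(set(universe) - set(ppt))
    if not ppt or not gpt:
        return IntegratedClassification(ppt, gpt, 1.0, False)
    try:
        lr = stats.logrank(pfs.loc[ppt], pfs.loc[gpt])
        p = lr.p_value
    except ValueError:
        p = 1.0
    return IntegratedClassification(ppt, gpt, float(p), bool(p < alpha))


# ---------------------------------------------------------------------------
# estimator facade


class SurvivalFeatureDiscretizer(BaseEstimator, TransformerMixin):
    """Select survival-associated features and emit ternary F-scores.

    ``fit`` runs the full screening funnel (status discretisation, gated
    log-rank scan, confounder refinement, expression-concordance
    refinement) on a (samples x features) matrix of raw copy-number ratios
    or batch-corrected beta values; ``transform`` discretises any cohort --
    including held-out samples -- with the training-derived features,
    cutoffs and survival directions.

    Parameters
    ----------
    modality : {"copy_number", "methylation"}
    thresholds : Thresholds, optional
    refine : bool
        Apply the confounder/fold-change refinements (on by default).

    Attributes
    ----------
    tests_ : list of FeatureTest for the retained features.
    report_ : all scanned tests, refinement flags included.
    cutoffs_ : per-feature beta quantile cutoffs (methylation only).
    funnel_ : dict of counts after each screening stage.
    """

    def __init__(self, modality: str = "copy_number",
                 thresholds: Thresholds | None = None, refine: bool = True):
        self.modality = modality
        self.thresholds = thresholds
        self.refine = refine

    def fit(self, X: pd.DataFrame, y: pd.DataFrame, *, clinical=None,
            expression: pd.DataFrame | None = None,
            feature_to_gene: dict | None = None):
        thr = self.thresholds or Thresholds()
        if self.modality == "copy_number":
            status = categorize_cn(X, thr)
            self.cutoffs_ = None
        else:
            status, self.cutoffs_ = categorize_meth(X, thr)
        tests = scan_features(status, y, self.modality, thr)
        funnel = {"scanned": X.shape[1], "selected": len(tests)}
        if self.refine:
            if clinical is None:
                raise ValueError("refinement requires the clinical table")
            tests, _ = refine_confounders(tests, clinical, self.modality,
                                          values=X, thr=thr)
            funnel["after_confounders"] = len(tests)
            if expression is not None:
                tests, _ = refine_foldchange(tests, expression,
                                             feature_to_gene, thr)
                funnel["after_foldchange"] = len(tests)
        self.tests_ = dedupe_tests(tests)
        funnel["final"] = len(self.tests_)
        self.funnel_ = funnel
        self.thresholds_ = thr
        return self

    def transform(self, X: pd.DataFrame) -> FScoreMatrix:
        if not hasattr(self, "tests_"):
            raise RuntimeError("fit before transform")
        feats = [t.feature_id for t in self.tests_]
        missing = [f for f in feats if f not in X.columns]
        if missing:
            warnings.warn(f"{len(missing)} selected features absent from the "
                          "input; their scores are 0")
            X = X.copy()
            for f in missing:
                X[f] = np.nan
        if self.modality == "copy_number":
            status = categorize_cn(X[feats], self.thresholds_)
        else:
            status, _ = categorize_meth(X[feats], self.thresholds_,
                                        cutoffs=self.cutoffs_)
        return assign_fscores(self.tests_, status)

    def fit_transform(self, X, y, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
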