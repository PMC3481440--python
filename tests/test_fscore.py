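"""F-score assignment, Jaccard distances, linkage and cluster labelling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chemoresponse.features import (GAIN, HYPER, HYPO, LOSS, MID, MISSING,
                                    NORMAL, FeatureTest)
from chemoresponse.fscore import (FScoreMatrix, assign_fscores,
                                  cluster_samples, complete_linkage,
                                  integrate_classifications, jaccard_distance)


def status_frame(codes, feature="f"):
    ids = [f"s{i}" for i in range(len(codes))]
    return pd.DataFrame({feature: np.array(codes, dtype=np.int8)}, index=ids)


def ftest(contrast, longer, feature="f", p=0.01, modality="copy_number"):
    return FeatureTest(feature, modality, contrast, p, longer, [], [])


class TestAssignFScores:
    def test_gain_contrast_normal_longer(self):
        # statuses: gain, normal, loss, missing
        status = status_frame([GAIN, NORMAL, LOSS, MISSING])
        f = assign_fscores([ftest("gain_vs_normal", "group2")], status)
        assert f.scores["f"].tolist() == [-1, 1, 0, 0]

    def test_loss_contrast_symmetric(self):
        status = status_frame([LOSS, NORMAL, GAIN, MISSING])
        f = assign_fscores([ftest("loss_vs_normal", "group1")], status)
        assert f.scores["f"].tolist() == [1, -1, 0, 0]

    def test_methylation_rest_longer(self):
        status = status_frame([HYPER, MID, HYPO, MISSING])
        f = assign_fscores(
            [ftest("hyper_vs_rest", "group2", modality="methylation")],
            status)
        assert f.scores["f"].tolist() == [-1, 1, 1, 0]

    def test_double_selection_uses_smaller_p(self):
        status = status_frame([GAIN, NORMAL, LOSS])
        tests = [ftest("gain_vs_normal", "group2", p=0.01),
                 ftest("loss_vs_normal", "group1", p=0.03)]
        f = assign_fscores(tests, status)
        assert f.scores["f"].tolist() == [-1, 1, 0]  # gain contrast won
        assert f.provenance.loc["f", "contrast"] == "gain_vs_normal"

    def test_direction_invariant_to_group_relabelling(self):
        status = status_frame([GAIN, GAIN, NORMAL, NORMAL])
        a = assign_fscores([ftest("gain_vs_normal", "group2")], status)
        # same science stated from the other group's perspective is the
        # opposite 'longer' label -> opposite scores, consistently
        b = assign_fscores([ftest("gain_vs_normal", "group1")], status)
        assert (a.scores["f"] == -b.scores["f"]).all()


class TestJaccard:
    def _f(self, rows):
        ids = [f"s{i}" for i in range(len(rows))]
        scores = pd.DataFrame(np.array(rows, dtype=np.int8), index=ids)
        return FScoreMatrix(scores, pd.DataFrame())

    def test_hand_examples(self):
        d, _ = jaccard_distance(self._f([[1, 0, -1], [1, 1, -1]]))
        assert d.iloc[0, 1] == pytest.approx(1 / 3)
        d, _ = jaccard_distance(self._f([[1, 1, 0], [-1, -1, 0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)
        d, _ = jaccard_distance(self._f([[1, 0, -1], [1, 0, -1]]))
        assert d.iloc[0, 1] == 0.0

    def test_all_zero_pair_flagged_distance_one(self):
        d, flagged = jaccard_distance(self._f([[0, 0], [0, 0], [1, 0]]))
        assert d.iloc[0, 1] == 1.0 and flagged[0, 1]
        assert d.iloc[0, 0] == 0.0 and not flagged[0, 0]

    def test_symmetry_and_range(self, rng):
        rows = rng.integers(-1, 2, (12, 7))
        d, _ = jaccard_distance(self._f(rows))
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert ((arr >= 0) & (arr <= 1)).all()
        assert np.allclose(np.diag(arr), 0)


def brute_force_complete_linkage(D, n_clusters):
    """Oracle: recompute every cluster pair's diameter from the original
    matrix at each step; merge the smallest (ties lexicographic)."""
    clusters = [[i] for i in range(len(D))]
    while len(clusters) > n_clusters:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            diam = max(D[i, j] for i in clusters[a] for j in clusters[b])
            key = (diam, min(clusters[a]), min(clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
        clusters.sort(key=min)
    labels = np.empty(len(D), int)
    for c, members in enumerate(sorted(clusters, key=min)):
        labels[members] = c
    return labels


class TestCompleteLinkage:
    def test_matches_brute_force_enumeration(self, rng):
        for n in (5, 6, 7, 8):
            for _ in range(10):
                D = rng.random((n, n))
                D = (D + D.T) / 2
                np.fill_diagonal(D, 0)
                for k in (2, 3):
                    mine, _ = complete_linkage(D, n_clusters=k)
                    oracle = brute_force_complete_linkage(D, k)
                    assert (mine == oracle).all()

    def test_matches_scipy_on_tie_free_distances(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        for _ in range(5):
            n = 15
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            mine, _ = complete_linkage(D, n_clusters=2)
            ref = fcluster(linkage(squareform(D, checks=False),
                                   method="complete"), 2, criterion="maxclust")
            # same partition up to label swap
            agreement = max(np.mean(mine == ref - 1),
                            np.mean(mine == 2 - ref))
            assert agreement == 1.0

    def test_permuting_samples_permutes_membership(self, rng):
        n = 10
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels, _ = complete_linkage(D, n_clusters=2)
        perm = rng.permutation(n)
        labels_p, _ = complete_linkage(D[np.ix_(perm, perm)], n_clusters=2)
        same = np.mean(labels_p == labels[perm])
        assert same in (0.0, 1.0)  # identical partition up to label swap
        # partition sizes must agree regardless of labelling
        assert sorted(np.bincount(labels_p)) == sorted(np.bincount(labels))


class TestClusterSamples:
    def _pfs(self, ids, times, events):
        return pd.DataFrame({"time": times, "event": events}, index=ids)

    def test_two_blocks_perfectly_separated(self):
        rows = [[1, 1, 1]] * 5 + [[-1, -1, -1]] * 4
        ids = [f"s{i}" for i in range(9)]
        f = FScoreMatrix(pd.DataFrame(np.array(rows, np.int8), index=ids),
                         pd.DataFrame())
        times = [100] * 5 + [10] * 4
        res = cluster_samples(f, self._pfs(ids, times, [True] * 9))
        assert set(res.ppt_ids) == set(ids[5:])  # unfavourable block is PPT
        assert set(res.gpt_ids) == set(ids[:5])

    def test_all_identical_profiles_degenerate(self):
        rows = [[1, 0, 1]] * 6
        ids = [f"s{i}" for i in range(6)]
        f = FScoreMatrix(pd.DataFrame(np.array(rows, np.int8), index=ids),
                         pd.DataFrame())
        res = cluster_samples(f, self._pfs(ids, [50] * 6, [True] * 6))
        assert "degenerate_no_enrichment" in res.flags
        assert not res.proposed

    def test_planted_cohort_ppt_recovery(self):
        """Most true cn_ppt training samples land in the CN-derived PPT
        cluster on a cohort where the amplified subtype is the only
        survival structure."""
        from chemoresponse.fscore import SurvivalFeatureDiscretizer
        from chemoresponse.selection import assign_cohorts, derive_pfs
        from chemoresponse.simulate import SimConfig, generate_cohort

        co = generate_cohort(SimConfig(
            n_samples=200, n_genes=300, n_cpg=50, n_planted_cpg=10,
            planted_segment=("1", 50, 25), frac_meth_ppt=0.0,
            frac_training=0.45, n_decoy_confounded=0, n_batches=6, seed=3))
        tr = assign_cohorts(co.clinical).training_ids
        pfs = derive_pfs(co.clinical).loc[tr]
        X = co.copy_number.to_samples_by_features().loc[tr]
        disc = SurvivalFeatureDiscretizer("copy_number", refine=False)
        f = disc.fit_transform(X, pfs)
        res = cluster_samples(f, pfs)
        truth = set(co.truth_labels.loc[tr][lambda s: s == "cn_ppt"].index)
        rec = len(truth & set(res.ppt_ids)) / len(truth)
        assert rec >= 0.8


class TestIntegration:
    def _pfs(self, ids):
        rng = np.random.default_rng(5)
        return pd.DataFrame({"time": rng.exponential(100, len(ids)),
                             "event": True}, index=ids)

    def _result(self, universe, ppt):
        from chemoresponse.fscore import ClusterResult
        gpt = [s for s in universe if s not in ppt]
        return ClusterResult(pd.Series(0, index=universe), list(ppt), gpt,
                             0.01, True, [])

    def test_union_of_overlapping_sets(self):
        ids = [f"s{i}" for i in range(85)]
        cn = self._result(ids, ids[:18])
        meth = self._result(ids, ids[10:40])  # overlap of 8 with cn
        out = integrate_classifications([cn, meth], self._pfs(ids))
        assert len(out.ppt_ids) == 40
        assert len(out.gpt_ids) == 45

    def test_disjoint_sets_add(self):
        ids = [f"s{i}" for i in range(30)]
        out = integrate_classifications(
            [self._result(ids, ids[:4]), self._result(ids, ids[4:9])],
            self._pfs(ids))
        assert len(out.ppt_ids) == 9

    def test_both_empty_all_gpt_no_proposal(self):
        ids = [f"s{i}" for i in range(10)]
        out = integrate_classifications(
            [self._result(ids, []), self._result(ids, [])], self._pfs(ids))
        assert out.ppt_ids == [] and len(out.gpt_ids) == 10
        assert not out.proposed
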