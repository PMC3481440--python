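"""Status discretisation, the gated log-rank scan, and candidate refinement."""

import numpy as np
import pandas as pd
import pytest

from chemoresponse.features import (GAIN, HYPER, HYPO, LOSS, MID, MISSING,
                                    NORMAL, FeatureTest, Thresholds,
                                    categorize_cn, categorize_meth,
                                    min_group_size, refine_confounders,
                                    refine_foldchange, scan_features)
from chemoresponse.io import ClinicalTable


def make_clinical(ages, stages):
    n = len(ages)
    samples = pd.DataFrame({
        "age": ages, "stage": stages, "batch": "b0",
        "event_day": 100.0, "event_observed": True,
        "last_followup_day": np.nan,
    }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    return ClinicalTable(samples)


class TestCategorize:
    def test_cn_printed_boundaries(self):
        X = pd.DataFrame({"g": [0.4, 0.41, -0.5, -0.51, np.nan]})
        out = categorize_cn(X)["g"].tolist()
        assert out == [NORMAL, GAIN, NORMAL, LOSS, MISSING]

    def test_meth_linear_interpolation_quantiles(self):
        vals = np.arange(1, 101) / 100.0
        X = pd.DataFrame({"c": vals})
        status, cutoffs = categorize_meth(X)
        assert cutoffs.loc["c", "lo"] == pytest.approx(25.75 / 100)
        assert cutoffs.loc["c", "hi"] == pytest.approx(75.25 / 100)
        got = status["c"].to_numpy()
        assert (got[vals < 0.2575] == HYPO).all()
        assert (got[vals > 0.7525] == HYPER).all()
        assert (got[(vals >= 0.2575) & (vals <= 0.7525)] == MID).all()

    def test_constant_feature_all_mid(self):
        status, _ = categorize_meth(pd.DataFrame({"c": [0.4] * 10}))
        assert (status["c"] == MID).all()

    def test_missing_excluded_from_quantiles_and_stays_missing(self):
        X = pd.DataFrame({"c": [0.1, 0.2, 0.5, 0.8, np.nan]})
        status, cutoffs = categorize_meth(X)
        assert status["c"].iloc[-1] == MISSING
        assert cutoffs.loc["c", "lo"] == pytest.approx(
            np.quantile([0.1, 0.2, 0.5, 0.8], 0.25))

    def test_stored_cutoffs_reused_for_new_cohort(self):
        train = pd.DataFrame({"c": np.linspace(0.2, 0.8, 20)})
        _, cutoffs = categorize_meth(train)
        test = pd.DataFrame({"c": [0.0, 0.5, 1.0]}, index=["a", "b", "c"])
        status, _ = categorize_meth(test, cutoffs=cutoffs)
        assert status["c"].tolist() == [HYPO, MID, HYPER]


class TestMinGroupSize:
    def test_printed_rule_at_study_size(self):
        assert min_group_size(85) == 13

    @pytest.mark.parametrize("n,expected", [(50, 13), (100, 15), (200, 30)])
    def test_ceiling_governs_other_sizes(self, n, expected):
        assert min_group_size(n) == expected


class TestScan:
    def _pfs(self, times, events, ids):
        return pd.DataFrame({"time": times, "event": events}, index=ids)

    def test_small_group_not_tested(self, rng):
        n = 85
        ids = [f"s{i}" for i in range(n)]
        codes = np.full((n, 1), NORMAL, dtype=np.int8)
        codes[:5, 0] = GAIN  # 5 < 13: gate fails
        status = pd.DataFrame(codes, index=ids, columns=["g"])
        pfs = self._pfs(rng.exponential(100, n), np.ones(n, bool), ids)
        assert scan_features(status, pfs, "copy_number") == []

    def test_planted_hazard_feature_selected_with_direction(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            n = 85
            ids = [f"s{i}" for i in range(n)]
            carriers = np.zeros(n, bool)
            carriers[:20] = True
            codes = np.where(carriers, GAIN, NORMAL).astype(np.int8)
            status = pd.DataFrame(codes[:, None], index=ids, columns=["g"])
            t = np.where(carriers, r.exponential(25, n), r.exponential(100, n))
            pfs = self._pfs(t, np.ones(n, bool), ids)
            tests = scan_features(status, pfs, "copy_number")
            if tests and tests[0].contrast == "gain_vs_normal" \
                    and tests[0].longer == "group2":
                hits += 1
        assert hits >= 18  # hazard x4 carriers: selected, normal group longer

    def test_methylation_contrasts_are_one_vs_rest(self, rng):
        n = 60
        ids = [f"s{i}" for i in range(n)]
        codes = np.array([HYPO] * 20 + [MID] * 20 + [HYPER] * 20,
                         dtype=np.int8)
        status = pd.DataFrame(codes[:, None], index=ids, columns=["c"])
        t = np.where(codes == HYPO, rng.exponential(20, n),
                     rng.exponential(120, n))
        pfs = self._pfs(t, np.ones(n, bool), ids)
        tests = scan_features(status, pfs, "methylation")
        by = {t_.contrast: t_ for t_ in tests}
        assert "hypo_vs_rest" in by
        assert len(by["hypo_vs_rest"].group2_ids) == 40


class TestRefinement:
    def _test_obj(self, g1, g2, modality="copy_number"):
        return FeatureTest("f", modality, "gain_vs_normal", 0.01, "group2",
                           list(g1), list(g2))

    def test_identical_age_distributions_never_dropped(self):
        ct = make_clinical(ages=[50] * 30, stages=["III"] * 30)
        ids = ct.sample_ids
        t = self._test_obj(ids[:15], ids[15:])
        kept, _ = refine_confounders([t], ct, "copy_number")
        assert kept and not t.flags

    def test_age_separated_groups_dropped(self):
        ct = make_clinical(ages=[40] * 15 + [75] * 15, stages=["III"] * 30)
        ids = ct.sample_ids
        t = self._test_obj(ids[:15], ids[15:])
        kept, report = refine_confounders([t], ct, "copy_number")
        assert kept == [] and "age_confounded" in report[0].flags

    def test_single_stage_cohort_vacuous_fisher(self):
        ct = make_clinical(ages=[50] * 26, stages=["III"] * 26)
        ids = ct.sample_ids
        t = self._test_obj(ids[:13], ids[13:])
        kept, _ = refine_confounders([t], ct, "copy_number")
        assert "stage_confounded" not in t.flags and kept

    def test_age_tracking_beta_decoy_dropped(self, rng):
        ages = rng.integers(35, 85, 40)
        ct = make_clinical(ages=ages, stages=["III"] * 40)
        ids = ct.sample_ids
        beta = pd.DataFrame(
            {"f": np.clip(ages / 100 + rng.normal(0, 0.02, 40), 0, 1)},
            index=ids)
        t = FeatureTest("f", "methylation", "hypo_vs_rest", 0.01, "group2",
                        ids[:15], ids[15:])
        kept, report = refine_confounders([t], ct, "methylation", values=beta)
        assert kept == [] and "age_confounded" in report[0].flags

    def test_foldchange_boundary_inclusive(self, rng):
        ids = [f"s{i}" for i in range(20)]
        shift = np.log2(1.3)
        expr = pd.DataFrame(
            {"f": [7.0 + shift] * 10 + [7.0] * 10}, index=ids)
        t = self._test_obj(ids[:10], ids[10:])
        kept, _ = refine_foldchange([t], expr)
        assert kept  # exactly 1.3x is retained

    def test_equal_means_dropped_and_unmapped_flagged(self):
        ids = [f"s{i}" for i in range(10)]
        expr = pd.DataFrame({"f": np.ones(10), "g": np.ones(10)}, index=ids)
        flat = self._test_obj(ids[:5], ids[5:])
        kept, _ = refine_foldchange([flat], expr)
        assert kept == [] and "fc_failed" in flat.flags
        orphan = FeatureTest("cg9", "methylation", "hypo_vs_rest", 0.01,
                             "group1", ids[:5], ids[5:])
        kept, report = refine_foldchange([orphan], expr, {"cg9": None})
        assert kept == [] and "no_gene" in orphan.flags


class TestFunnelMonotonicity:
    def test_each_stage_never_grows(self, small_cohort):
        from chemoresponse.batch import correct_methylation
        from chemoresponse.selection import assign_cohorts, derive_pfs

        co = small_cohort
        asg = assign_cohorts(co.clinical)
        tr = asg.training_ids
        pfs = derive_pfs(co.clinical).loc[tr]
        meth, _ = correct_methylation(co.methylation,
                                      co.clinical.samples["batch"])
        X = meth.to_samples_by_features().loc[tr]
        status, _ = categorize_meth(X)
        scanned = scan_features(status, pfs, "methylation")
        refined, _ = refine_confounders(
            [FeatureTest(**vars(t)) for t in scanned],
            co.clinical.subset(tr), "methylation", values=X)
        expr = co.expression.to_samples_by_features().loc[tr]
        final, _ = refine_foldchange(
            [FeatureTest(**vars(t)) for t in refined], expr, co.cpg_to_gene)
        assert len(scanned) >= len(refined) >= len(final)
        assert len(final) > 0  # planted CpGs make it through


class TestThresholdValidation:
    def test_inverted_quantiles_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(meth_lo_quantile=0.8, meth_hi_quantile=0.2)

    def test_fc_cut_must_exceed_one(self):
        with pytest.raises(ValueError):
            Thresholds(fc_cut=0.9)
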