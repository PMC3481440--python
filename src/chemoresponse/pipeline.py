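"""End-to-end orchestration: batch correction through differential expression.

Stage order: batch correction -> sample selection -> per-modality feature
screening -> F-score clustering -> integration -> weighted-KNN testing ->
differential expression.  A machine-readable :class:`RunReport` collects
the sample/feature funnels, cluster sizes, overlap counts, log-rank
p-values and differential-expression counts of a run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .batch import correct_expression, correct_methylation
from .diffexpr import differential_expression
from .features import Thresholds
from .fscore import (ClusterResult, SurvivalFeatureDiscretizer,
                     cluster_samples, integrate_classifications)
from .io import align_samples
from .knn import GOOD, POOR, KnnModel, WeightedJaccardKNN
from .selection import SelectionRules, assign_cohorts, derive_pfs
from .simulate import SimConfig, SyntheticCohort, generate_cohort, read_cohort


@dataclass
class PipelineConfig:
    """Run-level configuration; either simulate or point at a TSV file set."""

    simulate: bool = True
    input_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    rules: SelectionRules = field(default_factory=SelectionRules)
    thresholds: Thresholds = field(default_factory=Thresholds)
    k_neighbors: int = 3
    scale_estimator: str = "sd"
    de_fc_cut: float = 1.5
    de_alpha: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if self.seed is not None:
            self.sim.seed = self.seed


@dataclass
class RunReport:
    """Counts, p-values and configuration echo for one pipeline run."""

    seed: int
    version: str
    n_samples: int = 0
    n_training: int = 0
    n_testing: int = 0
    n_excluded: int = 0
    exclusion_reasons: dict = field(default_factory=dict)
    funnels: dict = field(default_factory=dict)        # modality -> stage counts
    cluster_sizes: dict = field(default_factory=dict)  # modality -> (ppt, gpt)
    train_overlap: int = 0
    train_ppt_total: int = 0
    train_gpt_total: int = 0
    test_cluster_sizes: dict = field(default_factory=dict)
    test_overlap: int = 0
    test_ppt_total: int = 0
    test_gpt_total: int = 0
    logrank_train: dict = field(default_factory=dict)  # modality + integrated
    logrank_test: float | None = None
    proposed: bool = False
    de_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (set, tuple)):
                return list(o)
            return str(o)

        text = json.dumps(dataclasses.asdict(self), indent=1, default=default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class PipelineResult:
    """Full in-memory artefacts of a run (the report plus fitted objects)."""

    report: RunReport
    cohort: SyntheticCohort
    pfs: pd.DataFrame
    assignment: object
    train_clusters: dict
    train_integrated: object | None
    discretizers: dict
    models: dict
    test_calls: dict
    test_integrated: object | None
    de: dict


def _fit_modality(modality, values, pfs, clinical, expression,
                  feature_to_gene, thresholds):
    disc = SurvivalFeatureDiscretizer(modality=modality, thresholds=thresholds)
    disc.fit(values, pfs, clinical=clinical, expression=expression,
             feature_to_gene=feature_to_gene)
    if not disc.tests_:
        return disc, None, None
    fscores = disc.transform(values)
    if fscores.scores.shape[0] < 2 or fscores.scores.shape[1] == 0:
        return disc, fscores, None
    result = cluster_samples(fscores, pfs)
    return disc, fscores, result


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full procedure and return report plus artefacts."""
    report = RunReport(seed=config.sim.seed, version=__version__,
                       config={"sim": dataclasses.asdict(config.sim),
                               "rules": dataclasses.asdict(config.rules),
                               "thresholds": dataclasses.asdict(config.thresholds),
                               "k_neighbors": config.k_neighbors,
                               "scale_estimator": config.scale_estimator})
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        # stage: inputs ---------------------------------------------------
        if config.simulate:
            cohort = generate_cohort(config.sim)
        else:
            if config.input_dir is None:
                raise ValueError("input_dir required when simulate=False")
            cohort = read_cohort(config.input_dir)
        batches = cohort.clinical.samples["batch"]

        # stage: batch correction (never applied to copy number) ----------
        expr_adj, _ = correct_expression(cohort.expression, batches,
                                         config.scale_estimator)
        meth_adj, _ = correct_methylation(cohort.methylation, batches)
        assert cohort.copy_number.modality == "copy_number"

        common, _ = align_samples(
            [expr_adj, cohort.copy_number, meth_adj], cohort.clinical)
        report.n_samples = len(common)

        # stage: sample selection -----------------------------------------
        assignment = assign_cohorts(cohort.clinical.subset(common),
                                    config.rules)
        pfs_all = derive_pfs(cohort.clinical)
        report.n_training = len(assignment.training_ids)
        report.n_testing = len(assignment.testing_ids)
        report.n_excluded = len(assignment.excluded)
        reasons: dict = {}
        for r in assignment.excluded.values():
            reasons[r] = reasons.get(r, 0) + 1
        report.exclusion_reasons = reasons
        train_ids = assignment.training_ids
        test_ids = assignment.testing_ids
        pfs_train = pfs_all.loc[train_ids]
        pfs_test = pfs_all.loc[test_ids]
        clin_train = cohort.clinical.subset(train_ids)
        expr_train = expr_adj.to_samples_by_features().loc[train_ids]
        cpg_map = cohort.cpg_to_gene if hasattr(cohort, "cpg_to_gene") else \
            dict(zip(meth_adj.annotations.index,
                     meth_adj.annotations["gene_symbol"]))

        # stage: feature selection + clustering per modality ---------------
        train_clusters: dict[str, ClusterResult | None] = {}
        discretizers: dict[str, SurvivalFeatureDiscretizer] = {}
        models: dict[str, KnnModel] = {}
        modality_inputs = {
            "copy_number": cohort.copy_number.to_samples_by_features(),
            "methylation": meth_adj.to_samples_by_features(),
        }
        for modality, values in modality_inputs.items():
            f2g = None if modality == "copy_number" else cpg_map
            disc, fscores, result = _fit_modality(
                modality, values.loc[train_ids], pfs_train, clin_train,
                expr_train, f2g, config.thresholds)
            report.funnels[modality] = disc.funnel_
            discretizers[modality] = disc
            train_clusters[modality] = result
            if result is not None:
                report.cluster_sizes[modality] = (len(result.ppt_ids),
                                                  len(result.gpt_ids))
                report.logrank_train[modality] = result.logrank_p
                # only classifications passing the survival gate are carried
                # forward to integration and testing
                if result.proposed:
                    labels = pd.Series(GOOD, index=fscores.scores.index)
                    labels.loc[result.ppt_ids] = POOR
                    knn = WeightedJaccardKNN(n_neighbors=config.k_neighbors)
                    knn.fit(fscores, labels)
                    models[modality] = KnnModel(disc, knn)

        # stage: integration of training classifications -------------------
        usable = [r for r in train_clusters.values()
                  if r is not None and r.proposed]
        train_integrated = None
        if usable:
            train_integrated = integrate_classifications(usable, pfs_train)
            ppt_sets = [set(r.ppt_ids) for r in usable]
            report.train_overlap = (len(set.intersection(*ppt_sets))
                                    if len(ppt_sets) > 1 else 0)
            report.train_ppt_total = len(train_integrated.ppt_ids)
            report.train_gpt_total = len(train_integrated.gpt_ids)
            report.logrank_train["integrated"] = train_integrated.logrank_p
            report.proposed = train_integrated.proposed

        # stage: weighted-KNN justification on the testing cohort ----------
        test_calls: dict[str, pd.DataFrame] = {}
        test_integrated = None
        if models and test_ids:
            poor_sets = []
            for modality, model in models.items():
                values = modality_inputs[modality].loc[test_ids]
                calls = model.classify(values)
                test_calls[modality] = calls
                poor = set(calls.index[calls["label"] == "poor"])
                poor_sets.append(poor)
                report.test_cluster_sizes[modality] = (
                    len(poor), len(test_ids) - len(poor))
            test_ppt = sorted(set.union(*poor_sets))
            test_gpt = sorted(set(test_ids) - set(test_ppt))
            report.test_overlap = (len(set.intersection(*poor_sets))
                                   if len(poor_sets) > 1 else 0)
            report.test_ppt_total = len(test_ppt)
            report.test_gpt_total = len(test_gpt)
            if test_ppt and test_gpt:
                from . import stats
                try:
                    report.logrank_test = stats.logrank(
                        pfs_test.loc[test_ppt], pfs_test.loc[test_gpt]).p_value
                except ValueError:
                    report.logrank_test = None
            from .fscore import IntegratedClassification
            test_integrated = IntegratedClassification(
                list(test_ppt), list(test_gpt),
                report.logrank_test if report.logrank_test is not None else 1.0,
                bool(report.logrank_test is not None
                     and report.logrank_test < 0.05))

        # stage: differential expression ------------------------------------
        de: dict[str, pd.DataFrame] = {}
        if train_integrated is not None and train_integrated.gpt_ids:
            gpt = train_integrated.gpt_ids
            for modality, result in train_clusters.items():
                if result is None or not result.proposed or \
                        len(result.ppt_ids) < 2 or len(gpt) < 2:
                    continue
                ppt = [s for s in result.ppt_ids if s not in gpt]
                table = differential_expression(
                    expr_train, ppt, gpt,
                    fc_cut=config.de_fc_cut, alpha=config.de_alpha)
                de[modality] = table
                report.de_counts[modality] = int(table["passes"].sum())
        caught = [str(w.message) for w in wlist]
    report.warnings = caught
    return PipelineResult(report, cohort, pfs_all, assignment, train_clusters,
                          train_integrated, discretizers, models, test_calls,
                          test_integrated, de)


def summarize(report: RunReport) -> str:
    """Human-readable funnel summary of a run report."""
    lines = [f"chemoresponse v{report.version} (seed {report.seed})",
             f"samples: {report.n_samples} total | "
             f"{report.n_training} training | {report.n_testing} testing | "
             f"{report.n_excluded} excluded"]
    for reason, cnt in sorted(report.exclusion_reasons.items()):
        lines.append(f"  excluded[{reason}]: {cnt}")
    for modality, funnel in report.funnels.items():
        stages = " -> ".join(f"{k}={v}" for k, v in funnel.items())
        lines.append(f"features[{modality}]: {stages}")
    for modality, (p_, g_) in report.cluster_sizes.items():
        p_val = report.logrank_train.get(modality)
        lines.append(f"training clusters[{modality}]: PPT={p_} GPT={g_} "
                     f"log-rank p={p_val:.3g}")
    if "integrated" in report.logrank_train:
        lines.append(
            f"training integrated: PPT={report.train_ppt_total} "
            f"(overlap {report.train_overlap}) GPT={report.train_gpt_total} "
            f"log-rank p={report.logrank_train['integrated']:.3g} "
            f"proposed={report.proposed}")
    else:
        lines.append("training integrated: no proposed classification")
    if report.logrank_test is not None:
        lines.append(f"testing: PPT={report.test_ppt_total} "
                     f"(overlap {report.test_overlap}) "
                     f"GPT={report.test_gpt_total} "
                     f"log-rank p={report.logrank_test:.3g}")
    for modality, cnt in report.de_counts.items():
        lines.append(f"differentially expressed genes[{modality} PPT vs GPT]: "
                     f"{cnt}")
    return "\n".join(lines)
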