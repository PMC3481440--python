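"""Progression-free survival derivation and cohort eligibility rules.

Samples become treatment-eligible when they are advanced stage (III/IV) and
each required drug (paclitaxel and carboplatin) was started within 30 days
of surgical resection and given for at least 4 cycles.  Eligible samples
split into a *training* cohort (never given any other drug before their
failure/censoring day) and a *testing* cohort (eligible but exposed to
additional drugs); everything else is excluded with a reason code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable

REQUIRED_DRUGS = ("paclitaxel", "carboplatin")


@dataclass
class SelectionRules:
    """Eligibility thresholds for the first-line combination therapy."""

    required_drugs: tuple = REQUIRED_DRUGS
    max_start_delay: int = 30   # days after surgery
    min_cycles: int = 4
    allowed_stages: tuple = ("III", "IV")

    def __post_init__(self):
        if self.max_start_delay < 0:
            raise ValueError("max_start_delay must be >= 0")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")


@dataclass
class CohortAssignment:
    """Disjoint training/testing/excluded partition with reason codes."""

    training_ids: list
    testing_ids: list
    excluded: dict = field(default_factory=dict)  # sample_id -> reason

    @property
    def excluded_ids(self) -> list:
        return list(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = ([(s, "training", "") for s in self.training_ids]
                + [(s, "testing", "") for s in self.testing_ids]
                + [(s, "excluded", r) for s, r in self.excluded.items()])
        return pd.DataFrame(rows, columns=["sample_id", "cohort", "reason"])


def derive_pfs(clinical: ClinicalTable) -> pd.DataFrame:
    """Progression-free survival per sample, in days from surgery.

    Time is the failure-event day when observed, otherwise the last
    follow-up day (censored).  Returns a DataFrame indexed by sample id
    with ``time`` and ``event`` columns.
    """
    s = clinical.samples
    obs = s["event_observed"].astype(bool)
    time = np.where(obs, s["event_day"], s["last_followup_day"]).astype(float)
    if (time < 0).any():
        bad = s.index[time < 0].tolist()
        raise ValueError(f"negative PFS for samples {bad[:5]}")
    return pd.DataFrame({"time": time, "event": obs.to_numpy()}, index=s.index)


def _drug_check(records: pd.DataFrame, drug: str, rules: SelectionRules):
    """Return a failure reason for ``drug`` or None when the rule is met."""
    recs = records[records["drug"] == drug]
    if recs.empty:
        return "missing_drug"
    ok = (recs["start_day"] <= rules.max_start_delay) & \
         (recs["cycles"] >= rules.min_cycles)
    if ok.any():
        return None
    if (recs["start_day"] <= rules.max_start_delay).any():
        return "cycles"
    return "start_delay"


def assign_cohorts(clinical: ClinicalTable,
                   rules: SelectionRules | None = None) -> CohortAssignment:
    """Partition samples into training / testing / excluded cohorts.

    Stage is screened first, then the per-drug timing and cycle rules for
    each required drug.  Among eligible samples, training membership
    requires that no non-required drug was started strictly before the
    failure (or censoring) day; the remaining eligible samples form the
    testing cohort.
    """
    rules = rules or SelectionRules()
    pfs = derive_pfs(clinical)
    training, testing, excluded = [], [], {}
    treatments = clinical.treatments
    for sid in clinical.sample_ids:
        stage = clinical.samples.at[sid, "stage"]
        if stage not in rules.allowed_stages:
            excluded[sid] = "stage"
            continue
        recs = treatments[treatments["sample_id"] == sid]
        reason = None
        for drug in rules.required_drugs:
            reason = _drug_check(recs, drug, rules)
            if reason is not None:
                break
        if reason is not None:
            excluded[sid] = reason
            continue
        others = recs[~recs["drug"].isin(rules.required_drugs)]
        horizon = pfs.at[sid, "time"]
        if (others["start_day"] < horizon).any():
            testing.append(sid)
        else:
            training.append(sid)
    if not training or not testing:
        warnings.warn("assign_cohorts: empty training or testing cohort")
    return CohortAssignment(training, testing, excluded)
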