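"""Data model and TSV readers/writers for omics matrices and clinical tables.

Matrices are stored features-as-rows, samples-as-columns with a header row of
sample identifiers and ``NA`` as the missing-value token.  Estimator-facing
code in this package works on the transposed (samples x features) orientation;
:meth:`OmicsMatrix.to_samples_by_features` converts.

Dates are integer day offsets from surgical resection (day 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

MODALITIES = ("expression", "copy_number", "methylation")


class ValidationError(ValueError):
    """Raised when an input file or table violates the data contract."""


@dataclass
class OmicsMatrix:
    """A feature-by-sample numeric matrix with per-feature annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Features as rows (index = feature ids), samples as columns.  Missing
        entries are ``NaN``.
    modality : str
        One of ``expression`` (log2 values), ``copy_number`` (log2 ratios)
        or ``methylation`` (beta values in [0, 1]).
    annotations : pandas.DataFrame, optional
        Indexed by feature id; typical columns are ``gene_symbol``,
        ``chromosome``, ``position`` and, for methylation, ``cpg_id``.
    """

    values: pd.DataFrame
    modality: str
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if self.modality == "methylation":
            vals = self.values.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                r, c = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValidationError(
                    f"beta value out of [0,1]: feature {idx[r]!r}, "
                    f"sample {cols[c]!r}, value {vals[r, c]}"
                )
        if self.annotations is not None:
            missing = idx.difference(self.annotations.index)
            if len(missing):
                raise ValidationError(
                    f"features without annotation: {missing[:5].tolist()}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_samples_by_features(self) -> pd.DataFrame:
        """Transposed view (samples as rows) for estimator-style APIs."""
        return self.values.T

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(sample_ids)], self.modality,
                           self.annotations)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates plus a long-format treatment table.

    ``samples`` is indexed by sample id with columns ``age`` (years),
    ``stage`` (``III``/``IV``/``other``), ``batch``, ``event_day``,
    ``event_observed`` and ``last_followup_day``; day fields count from
    surgery (day 0).  ``treatments`` has one row per administered drug:
    ``sample_id``, ``drug``, ``start_day``, ``cycles``.
    """

    samples: pd.DataFrame
    treatments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "drug", "start_day", "cycles"]))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        req = {"age", "stage", "batch", "event_day", "event_observed",
               "last_followup_day"}
        missing = req - set(self.samples.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns {sorted(missing)}")
        if self.samples.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        s = self.samples
        obs = s["event_observed"].astype(bool)
        bad = obs & ~(s["event_day"].fillna(-1) >= 0)
        if bad.any():
            raise ValidationError(
                f"observed event without nonnegative event_day: "
                f"{s.index[bad][:5].tolist()}")
        bad = ~obs & ~(s["last_followup_day"].fillna(-1) >= 0)
        if bad.any():
            raise ValidationError(
                f"censored sample without nonnegative last_followup_day: "
                f"{s.index[bad][:5].tolist()}")
        unknown = set(self.treatments["sample_id"]) - set(s.index)
        if unknown:
            raise ValidationError(
                f"treatment rows for unknown samples: {sorted(unknown)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def treatments_for(self, sample_id: str) -> pd.DataFrame:
        t = self.treatments
        return t[t["sample_id"] == sample_id]

    def subset(self, sample_ids) -> "ClinicalTable":
        ids = list(sample_ids)
        t = self.treatments[self.treatments["sample_id"].isin(ids)]
        return ClinicalTable(self.samples.loc[ids], t.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path, modality: str, annotations_path=None,
                average_duplicate_genes: bool = False) -> OmicsMatrix:
    """Read a feature-by-sample TSV matrix.

    ``NA`` tokens become missing values.  With ``average_duplicate_genes``
    (used for gene-annotated copy-number ratios) rows sharing a
    ``gene_symbol`` annotation are averaged into one gene-level row.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0,
                          na_values=[NA_TOKEN])
        ann.index = ann.index.astype(str)
    if average_duplicate_genes and ann is not None and "gene_symbol" in ann:
        sym = ann.loc[df.index, "gene_symbol"]
        df = df.groupby(sym).mean()
        ann = ann.drop_duplicates(subset=["gene_symbol"]).set_index("gene_symbol")
    try:
        return OmicsMatrix(df.astype(float), modality, ann)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep=NA_TOKEN,
                         index_label="feature_id")
    if matrix.annotations is not None:
        ann_path = Path(path).with_name("features_" + Path(path).name)
        matrix.annotations.to_csv(ann_path, sep="\t", na_rep=NA_TOKEN,
                                  index_label="feature_id")


def read_clinical(clinical_path, treatments_path=None) -> ClinicalTable:
    """Read the per-sample clinical TSV and its long-format treatment table."""
    samples = pd.read_csv(clinical_path, sep="\t", index_col=0,
                          na_values=[NA_TOKEN])
    samples.index = samples.index.astype(str)
    if "event_observed" in samples:
        samples["event_observed"] = samples["event_observed"].astype(bool)
    if treatments_path is not None:
        treatments = pd.read_csv(treatments_path, sep="\t",
                                 na_values=[NA_TOKEN],
                                 dtype={"sample_id": str, "drug": str})
    else:
        treatments = pd.DataFrame(
            columns=["sample_id", "drug", "start_day", "cycles"])
    return ClinicalTable(samples, treatments)


def write_clinical(clinical: ClinicalTable, clinical_path, treatments_path) -> None:
    clinical.samples.to_csv(clinical_path, sep="\t", na_rep=NA_TOKEN,
                            index_label="sample_id")
    clinical.treatments.to_csv(treatments_path, sep="\t", na_rep=NA_TOKEN,
                               index=False)


def align_samples(matrices, clinical: ClinicalTable | None = None):
    """Intersect sample ids across matrices (and clinical) in sorted order.

    Returns ``(common_ids, dropped)`` where ``dropped`` maps each input's
    label to the ids it contributed that are not in the intersection.
    Raises :class:`ValidationError` when the intersection is empty.
    """
    sets: dict[str, set] = {}
    for i, m in enumerate(matrices):
        sets[f"{m.modality}[{i}]"] = set(m.sample_ids)
    if clinical is not None:
        sets["clinical"] = set(clinical.sample_ids)
    if not sets:
        raise ValidationError("no inputs to align")
    common = set.intersection(*sets.values())
    if not common:
        raise ValidationError("empty sample intersection across inputs")
    dropped = {name: sorted(ids - common) for name, ids in sets.items()
               if ids - common}
    for name, ids in dropped.items():
        warnings.warn(f"align_samples: dropped {len(ids)} samples from {name}")
    return sorted(common), dropped
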