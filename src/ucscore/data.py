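"""Cohort I/O, validation, labeling-kit harmonization, and activity classes.

The package works on three plain-text files:

* an expression matrix (TSV): first column ``probe_id``, remaining columns
  sample ids, values log2 intensities;
* a sample table (CSV) with the clinical covariates per biopsy;
* a probe annotation (CSV): ``probe_id,gene_symbol,flags`` with
  semicolon-delimited interest flags.

Everything downstream consumes the validated :class:`CohortBundle`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIAGNOSES = ("UC", "IBDU", "control")
KITS = ("kit_A", "kit_B")

SAMPLE_COLUMNS = [
    "sample_id",
    "patient_id",
    "diagnosis",
    "endoscopic_mayo",
    "partial_mayo",
    "total_mayo",
    "pga",
    "fecal_calprotectin",
    "labeling_kit",
    "center",
    "status_code",
]


class CohortValidationError(ValueError):
    """Raised when the cohort files are inconsistent or malformed."""


@dataclass
class CohortBundle:
    """Validated expression matrix + sample table + probe annotation.

    ``matrix`` is a probes x samples DataFrame of log2 intensities;
    ``samples`` is indexed by sample id; ``annotation`` by probe id.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        validate_bundle(self)

    @property
    def control_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["diagnosis"] == "control"])

    @property
    def biopsy_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["diagnosis"] != "control"])


@dataclass
class ClassLabels:
    """Binary activity classes: active <=> endoscopic Mayo subscore > 1."""

    labels: pd.Series  # sample id -> "active" / "inactive"
    cohort_tag: str = "Mayo_Prob_1"

    @property
    def included(self) -> list[str]:
        return list(self.labels.index)

    @property
    def active_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == "active"])

    @property
    def inactive_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == "inactive"])

    def binary(self) -> pd.Series:
        """1 for active, 0 for inactive, same index order as labels."""
        return (self.labels == "active").astype(int)


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise CohortValidationError(f"duplicated {what}: {dups}")


def validate_bundle(bundle: CohortBundle) -> None:
    m, s, a = bundle.matrix, bundle.samples, bundle.annotation
    _check_unique(m.index, "probe ids in matrix")
    _check_unique(m.columns, "sample ids in matrix")
    _check_unique(s.index, "sample ids in sample table")

    matrix_samples = set(map(str, m.columns))
    table_samples = set(map(str, s.index))
    if matrix_samples != table_samples:
        only_m = sorted(matrix_samples - table_samples)
        only_t = sorted(table_samples - matrix_samples)
        raise CohortValidationError(
            "sample ids disagree between matrix and sample table; "
            f"matrix-only: {only_m}; table-only: {only_t}"
        )

    values = m.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad_rows = m.index[~np.isfinite(values).all(axis=1)][:20].tolist()
        raise CohortValidationError(
            f"non-finite expression values in probes: {bad_rows}"
        )

    missing_annot = m.index.difference(a.index)
    if len(missing_annot) > 0:
        raise CohortValidationError(
            f"probes missing from annotation: {sorted(missing_annot[:20].tolist())}"
        )

    bad_dx = set(s["diagnosis"].unique()) - set(DIAGNOSES)
    if bad_dx:
        raise CohortValidationError(f"unknown diagnosis values: {sorted(bad_dx)}")

    noncontrol = s[s["diagnosis"] != "control"]
    missing_mayo = noncontrol.index[noncontrol["endoscopic_mayo"].isna()]
    if len(missing_mayo) > 0:
        raise CohortValidationError(
            "non-control samples without an endoscopic Mayo subscore: "
            f"{sorted(missing_mayo.tolist())}"
        )

    bad_kit = set(s["labeling_kit"].unique()) - set(KITS)
    if bad_kit:
        raise CohortValidationError(f"unknown labeling kits: {sorted(bad_kit)}")


def load_cohort(matrix_path, samples_path, annotation_path) -> CohortBundle:
    """Read the three cohort files, validate them, and log a load report."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    samples = pd.read_csv(samples_path, dtype={"sample_id": str, "patient_id": str})
    missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise CohortValidationError(f"sample table missing columns: {sorted(missing_cols)}")
    samples = samples.set_index("sample_id")

    annotation = pd.read_csv(annotation_path, dtype=str).fillna({"gene_symbol": "", "flags": ""})
    if "probe_id" not in annotation.columns:
        raise CohortValidationError("annotation file must have a probe_id column")
    annotation = annotation.set_index("probe_id")
    if "flags" not in annotation.columns:
        annotation["flags"] = ""

    bundle = CohortBundle(matrix=matrix, samples=samples, annotation=annotation)

    dx_counts = samples["diagnosis"].value_counts().to_dict()
    mayo_counts = (
        samples.loc[samples["diagnosis"] != "control", "endoscopic_mayo"]
        .value_counts()
        .sort_index()
        .to_dict()
    )
    logger.info(
        "loaded cohort: %d probes x %d samples; diagnoses %s; Mayo subscores %s",
        matrix.shape[0], matrix.shape[1], dx_counts, mayo_counts,
    )
    return bundle


def write_cohort(bundle: CohortBundle, matrix_path, samples_path, annotation_path) -> None:
    """Write the bundle back out in the canonical TSV/CSV formats."""
    bundle.matrix.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    bundle.samples.rename_axis("sample_id").to_csv(samples_path)
    bundle.annotation.rename_axis("probe_id").to_csv(annotation_path)


def apply_kit_correction(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Harmonize labeling-kit batches by per-probe additive mean-matching.

    For every probe, the non-reference kit's samples receive the additive
    log2 offset that equalizes the two per-kit probe means (equivalently a
    multiplicative linear-scale correction factor).  The reference kit is
    the one with more samples (ties favour kit_A).  A single-kit matrix is
    returned unchanged.  Within-kit contrasts are preserved exactly, and the
    operation is idempotent.
    """
    kits = samples.loc[matrix.columns, "labeling_kit"]
    counts = kits.value_counts()
    if len(counts) < 2:
        return matrix.copy()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise CohortValidationError(
            f"kit correction needs >= 2 samples per kit; too few in: {small}"
        )
    if counts.get("kit_A", 0) >= counts.get("kit_B", 0):
        reference, other = "kit_A", "kit_B"
    else:
        reference, other = "kit_B", "kit_A"

    ref_cols = kits.index[kits == reference]
    oth_cols = kits.index[kits == other]
    offset = matrix[ref_cols].mean(axis=1) - matrix[oth_cols].mean(axis=1)

    corrected = matrix.copy()
    corrected.loc[:, oth_cols] = corrected.loc[:, oth_cols].add(offset, axis=0)
    return corrected


def define_activity_classes(samples: pd.DataFrame, include_ibdu: bool) -> ClassLabels:
    """Binary endoscopic-activity classes on the >1 vs <=1 subscore threshold.

    ``include_ibdu=False`` restricts to UC biopsies (the Mayo_Prob_1 cohort);
    ``include_ibdu=True`` adds the IBDU biopsies (Mayo_Prob_2).  Controls are
    never included.
    """
    wanted = ("UC", "IBDU") if include_ibdu else ("UC",)
    sub = samples[samples["diagnosis"].isin(wanted)]
    if sub["endoscopic_mayo"].isna().any():
        bad = sub.index[sub["endoscopic_mayo"].isna()].tolist()
        raise CohortValidationError(f"samples without Mayo subscore: {bad}")
    labels = pd.Series(
        np.where(sub["endoscopic_mayo"] > 1, "active", "inactive"),
        index=sub.index,
        name="activity_class",
    )
    n_active = int((labels == "active").sum())
    n_inactive = len(labels) - n_active
    if n_active == 0 or n_inactive == 0:
        raise CohortValidationError(
            f"degenerate activity classes: {n_active} active / {n_inactive} inactive"
        )
    tag = "Mayo_Prob_2" if include_ibdu else "Mayo_Prob_1"
    return ClassLabels(labels=labels, cohort_tag=tag)
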