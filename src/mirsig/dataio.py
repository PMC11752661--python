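"""On-disk formats and validated in-memory containers.

A study is represented by three text files:

* signal matrix — TSV, probe rows, sample columns, first column ``probe_id``,
  linear-scale non-negative signals; empty cells and ``NA`` are missing,
* probe annotation — TSV with columns ``probe_id`` and ``probe_class``
  (``target`` / ``negative_control`` / ``internal_control``),
* sample metadata — CSV with one row per sample (cohort, analysis set,
  tumor scores, CA19-9/CEA, processing times, platelet count).

All downstream modules consume the :class:`SignalMatrix` and
:class:`NormalizedMatrix` containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

PROBE_CLASSES = ("target", "negative_control", "internal_control")

#: internal-control miRNAs used for per-sample normalization
DEFAULT_INTERNAL_CONTROLS = ("miR-149-3p", "miR-2861", "miR-4463")

COHORTS = ("healthy", "pbca")
ANALYSIS_SETS = ("exploratory", "validation", "independent_validation", "timecourse")

_SCORE_RANGES = {"ct_score": (0, 4), "cn_score": (0, 2), "cm_score": (0, 2)}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class SignalMatrix:
    """Raw probe × sample signal matrix with probe-class annotation.

    ``values`` holds linear-scale signals with ``NaN`` as the missing marker;
    ``annotation`` maps each probe_id to its probe_class; ``metadata`` is one
    row per sample, indexed by sample_id, aligned with the value columns.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.values.index.name = "probe_id"
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicate probe_id(s): {dups}")
        ann = self.annotation.set_index("probe_id") if "probe_id" in self.annotation.columns else self.annotation
        unknown = set(ann.index) - set(self.values.index)
        if unknown:
            raise DataError(f"annotated probe(s) absent from the matrix: {sorted(unknown)}")
        missing_ann = set(self.values.index) - set(ann.index)
        if missing_ann:
            raise DataError(f"probe(s) without annotation: {sorted(missing_ann)}")
        bad = set(ann["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise DataError(f"unknown probe_class values: {sorted(bad)}")
        ann = ann.loc[self.values.index]
        ann.index.name = "probe_id"
        self.annotation = ann.reset_index()
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise DataError("negative signal values are not allowed")
        if self.metadata is not None:
            absent = [s for s in self.values.columns if s not in self.metadata.index]
            if absent:
                raise DataError(f"sample(s) in matrix absent from metadata: {absent}")
            self.metadata = self.metadata.loc[self.values.columns]

    @property
    def probe_class(self) -> pd.Series:
        return self.annotation.set_index("probe_id")["probe_class"]

    def probe_ids(self, probe_class: str) -> list[str]:
        cls = self.probe_class
        return list(cls.index[cls == probe_class])

    @property
    def target_ids(self) -> list[str]:
        return self.probe_ids("target")

    @property
    def negative_control_ids(self) -> list[str]:
        return self.probe_ids("negative_control")

    @property
    def internal_control_ids(self) -> list[str]:
        return self.probe_ids("internal_control")


@dataclass
class NormalizedMatrix:
    """log2 target-miRNA levels after internal-control normalization.

    ``values``: miRNA × sample log2 expression (controls excluded, no missing);
    ``intcon``: per-sample mean of the log2 internal-control signals, a proxy
    for total serum miRNA concentration.
    """

    values: pd.DataFrame
    intcon: pd.Series
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.intcon.index):
            raise DataError("values columns and intcon index disagree")
        if self.values.isna().any().any():
            raise DataError("normalized values must not contain missing entries")

    def subset_samples(self, sample_ids) -> "NormalizedMatrix":
        meta = None if self.metadata is None else self.metadata.loc[sample_ids]
        return NormalizedMatrix(self.values[sample_ids], self.intcon[sample_ids], meta)


def read_signal_matrix(path, annotation_path, metadata_path=None) -> SignalMatrix:
    """Read a signal matrix TSV plus its probe annotation (and metadata CSV).

    ``NA`` and empty cells parse to missing; probe and sample order is
    preserved as written.
    """
    values = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA", ""])
    values.columns = values.columns.astype(str)
    annotation = pd.read_csv(annotation_path, sep="\t")
    metadata = read_sample_metadata(metadata_path) if metadata_path is not None else None
    return SignalMatrix(values=values, annotation=annotation, metadata=metadata)


def write_signal_matrix(matrix: SignalMatrix, path, annotation_path, metadata_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")
    matrix.annotation.to_csv(annotation_path, sep="\t", index=False)
    if metadata_path is not None and matrix.metadata is not None:
        matrix.metadata.to_csv(metadata_path, index_label="sample_id")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata CSV.

    Linear and log2 CA19-9 are mutually derivable: whichever is present is
    used to fill the other (CA19-9 in U/mL, log base 2).
    """
    meta = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    bad_cohort = set(meta["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise DataError(f"unknown cohort value(s): {sorted(bad_cohort)}")
    if "analysis_set" in meta.columns:
        bad_set = set(meta["analysis_set"]) - set(ANALYSIS_SETS)
        if bad_set:
            raise DataError(f"unknown analysis_set value(s): {sorted(bad_set)}")
    if "disease_score" not in meta.columns:
        meta["disease_score"] = (meta["cohort"] == "pbca").astype(int)
    if not meta["disease_score"].isin([0, 1]).all():
        raise DataError("disease_score must be 0 or 1")
    for col, (lo, hi) in _SCORE_RANGES.items():
        if col in meta.columns:
            vals = meta[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                bad = meta.index[meta[col].notna() & ~meta[col].between(lo, hi)].tolist()
                raise DataError(f"{col} outside {lo}..{hi} for sample(s): {bad}")
            healthy = meta["cohort"] == "healthy"
            if (meta.loc[healthy, col].fillna(0) != 0).any():
                bad = meta.index[healthy & (meta[col].fillna(0) != 0)].tolist()
                raise DataError(f"healthy sample(s) with nonzero {col}: {bad}")
    has_lin = "ca199_linear" in meta.columns
    has_log = "log_ca199" in meta.columns
    if has_lin and not has_log:
        meta["log_ca199"] = np.log2(meta["ca199_linear"])
    elif has_log and not has_lin:
        meta["ca199_linear"] = np.exp2(meta["log_ca199"])
    elif has_lin and has_log:
        fill = meta["log_ca199"].isna() & meta["ca199_linear"].notna()
        meta.loc[fill, "log_ca199"] = np.log2(meta.loc[fill, "ca199_linear"])
        fill = meta["ca199_linear"].isna() & meta["log_ca199"].notna()
        meta.loc[fill, "ca199_linear"] = np.exp2(meta.loc[fill, "log_ca199"])
    return meta


def make_annotation(
    target_ids,
    negative_control_ids=(),
    internal_control_ids=DEFAULT_INTERNAL_CONTROLS,
) -> pd.DataFrame:
    """Build a probe-annotation table from id lists."""
    rows = (
        [(p, "target") for p in target_ids]
        + [(p, "negative_control") for p in negative_control_ids]
        + [(p, "internal_control") for p in internal_control_ids]
    )
    return pd.DataFrame(rows, columns=["probe_id", "probe_class"])


def load_config(path) -> dict:
    """Load a YAML configuration of thresholds and seeds."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
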