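"""Shared data model and tabular I/O.

All matrices are CpG-by-sample pandas DataFrames wrapped in thin validated
containers.  Methylation is carried on two scales: beta (fraction methylated,
in [0, 1]) and M (log2 of the methylated/unmethylated ratio).  Sample metadata
lives in a :class:`SampleSheet` that knows the pre/post pairing structure of
the cohort; probe metadata lives in a :class:`CpGAnnotation`.

File conventions
----------------
* beta / M / detection-p matrices: CSV or TSV, first column ``cpg_id``,
  header row of sample ids, numeric cells (empty = missing).
* sample sheet and annotation: CSV with the exact column names documented on
  the corresponding class.
* gene sets: GMT (set name, description, then tab-separated gene symbols).

Categorical labels are normalized to lower snake case at read time, so
"Partial Response" and "partial_response" are the same level.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "MValueMatrix",
    "DetectionPMatrix",
    "SampleSheet",
    "CpGAnnotation",
    "ValidationError",
    "read_beta_matrix",
    "read_detection_p_matrix",
    "read_sample_sheet",
    "read_cpg_annotation",
    "read_gmt",
    "read_normal_reference",
    "write_results_table",
    "normalize_label",
]

TIMEPOINTS = ("pre", "post")
SURVIVAL_GROUPS = ("survivor", "non_survivor")
RESPONSES = ("partial_response", "stable_disease")
GENOMIC_CONTEXTS = ("promoter", "gene_body", "intergenic")
ISLAND_STATUSES = ("CGI", "nonCGI")
PROBE_TYPES = ("I", "II")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


def normalize_label(value: object) -> str:
    """Normalize a categorical label to lower snake case.

    ``"Partial Response"`` → ``"partial_response"``; hyphens and repeated
    whitespace collapse to single underscores.
    """
    s = str(value).strip()
    s = re.sub(r"[\s\-]+", "_", s)
    return s.lower()


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


# ---------------------------------------------------------------------------
# matrix containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _CpGSampleMatrix:
    """Base container: CpGs as rows, samples as columns, float values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        _check_unique(df.index, "cpg_id")
        _check_unique(df.columns, "sample_id")
        object.__setattr__(self, "values", df.astype(float))
        self._validate_values()

    def _validate_values(self) -> None:  # overridden by subclasses
        pass

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]):
        return type(self)(self.values.loc[:, list(sample_ids)])

    def subset_cpgs(self, cpg_ids: Iterable[str]):
        return type(self)(self.values.loc[list(cpg_ids)])


def _name_offender(df: pd.DataFrame, bad: np.ndarray) -> str:
    i, j = np.argwhere(bad)[0]
    return f"CpG {df.index[i]!r}, sample {df.columns[j]!r} (value {df.iat[i, j]!r})"


class BetaMatrix(_CpGSampleMatrix):
    """Methylation beta values in [0, 1]; NaN marks a missing measurement."""

    def _validate_values(self) -> None:
        arr = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            raise ValidationError(
                "beta value outside [0, 1] at " + _name_offender(self.values, bad)
            )


class MValueMatrix(_CpGSampleMatrix):
    """Methylation M-values (log2 beta/(1-beta)); any finite real is legal."""

    def _validate_values(self) -> None:
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            bad = np.isinf(arr)
            raise ValidationError(
                "non-finite M value at " + _name_offender(self.values, bad)
            )


class DetectionPMatrix(_CpGSampleMatrix):
    """Per-probe, per-sample detection p-values in [0, 1]."""

    def _validate_values(self) -> None:
        arr = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            raise ValidationError(
                "detection p outside [0, 1] at " + _name_offender(self.values, bad)
            )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

_REQUIRED_SHEET_COLS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "survival_group",
    "survival_time",
    "event",
)
_OPTIONAL_SHEET_COLS = ("response", "treatment", "subtype")


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample clinical metadata with the pre/post pairing index.

    Required columns: ``sample_id``, ``patient_id``, ``timepoint``
    (pre/post), ``survival_group`` (survivor/non_survivor),
    ``survival_time`` (years, ≥ 0), ``event`` (0/1).  Optional:
    ``response``, ``treatment``, ``subtype`` and any extra clinical columns.
    At most one pre and one post sample per patient; unpaired patients are
    legal and flagged, not rejected.
    """

    data: pd.DataFrame
    pairing: Mapping[str, dict] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _REQUIRED_SHEET_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["patient_id"] = df["patient_id"].astype(str)
        _check_unique(pd.Index(df["sample_id"]), "sample_id")

        for col, levels in (
            ("timepoint", TIMEPOINTS),
            ("survival_group", SURVIVAL_GROUPS),
        ):
            df[col] = df[col].map(normalize_label)
            bad = sorted(set(df[col]) - set(levels))
            if bad:
                raise ValidationError(f"unknown {col} label(s): {bad}")
        if "response" in df.columns:
            known = df["response"].notna()
            df.loc[known, "response"] = df.loc[known, "response"].map(normalize_label)
            bad = sorted(set(df.loc[known, "response"]) - set(RESPONSES))
            if bad:
                raise ValidationError(f"unknown response label(s): {bad}")
        if "treatment" in df.columns:
            known = df["treatment"].notna()
            df.loc[known, "treatment"] = df.loc[known, "treatment"].map(normalize_label)

        df["survival_time"] = df["survival_time"].astype(float)
        if (df["survival_time"] < 0).any():
            raise ValidationError("negative survival_time")
        if not df["event"].isin((0, 1)).all():
            bad = sorted(set(df["event"]) - {0, 1})
            raise ValidationError(f"event must be 0/1, got {bad}")
        df["event"] = df["event"].astype(int)

        counts = df.groupby(["patient_id", "timepoint"]).size()
        dup = counts[counts > 1]
        if len(dup):
            raise ValidationError(
                f"more than one sample per patient/timepoint: {dup.index.tolist()}"
            )
        df = df.reset_index(drop=True)
        pairing: dict[str, dict] = {}
        for pid, grp in df.groupby("patient_id"):
            pairing[pid] = dict(zip(grp["timepoint"], grp["sample_id"]))
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "pairing", pairing)

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def paired_patients(self) -> list[str]:
        """Patients with both a pre and a post sample, in sheet order."""
        seen = dict.fromkeys(self.data["patient_id"])
        return [p for p in seen if set(self.pairing[p]) == {"pre", "post"}]

    def unpaired_patients(self) -> list[str]:
        seen = dict.fromkeys(self.data["patient_id"])
        return [p for p in seen if set(self.pairing[p]) != {"pre", "post"}]

    def samples_where(self, **conditions) -> pd.DataFrame:
        """Rows matching all equality conditions, e.g. ``timepoint='pre'``."""
        df = self.data
        for col, val in conditions.items():
            df = df[df[col] == val]
        return df

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = set(sample_ids)
        return SampleSheet(self.data[self.data["sample_id"].isin(ids)])


# ---------------------------------------------------------------------------
# CpG annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGAnnotation:
    """Probe annotation keyed by ``cpg_id``.

    Columns: ``gene`` (symbol or empty), ``genomic_context``
    (promoter/gene_body/intergenic), ``island`` (CGI/nonCGI), ``probe_type``
    (I/II), optional ``chrom``/``pos`` (1-based, carried but never computed
    on).  Intergenic probes must have an empty gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "cpg_id" in df.columns:
            df = df.set_index("cpg_id")
        _check_unique(df.index, "cpg_id")
        required = ("gene", "genomic_context", "island")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        df["gene"] = df["gene"].fillna("").astype(str)
        df["genomic_context"] = df["genomic_context"].map(normalize_label)
        bad = sorted(set(df["genomic_context"]) - set(GENOMIC_CONTEXTS))
        if bad:
            raise ValidationError(f"unknown genomic_context label(s): {bad}")
        bad = sorted(set(df["island"]) - set(ISLAND_STATUSES))
        if bad:
            raise ValidationError(f"unknown island label(s): {bad}")
        if "probe_type" not in df.columns or df["probe_type"].isna().all():
            warnings.warn("probe_type missing from annotation; defaulting to 'II'")
            df["probe_type"] = "II"
        df["probe_type"] = df["probe_type"].fillna("II")
        bad = sorted(set(df["probe_type"]) - set(PROBE_TYPES))
        if bad:
            raise ValidationError(f"unknown probe_type label(s): {bad}")
        offenders = df[(df["genomic_context"] == "intergenic") & (df["gene"] != "")]
        if len(offenders):
            raise ValidationError(
                f"intergenic probes must have empty gene: {offenders.index[:5].tolist()}"
            )
        object.__setattr__(self, "data", df)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.data.index

    def subset(self, cpg_ids: Iterable[str]) -> "CpGAnnotation":
        return CpGAnnotation(self.data.loc[list(cpg_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if Path(path).suffix.lower() in {".tsv", ".txt"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _read_matrix_frame(path, dialect: str | None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sep_for(Path(path), dialect), float_precision="round_trip"
    )
    if df.columns[0] != "cpg_id":
        raise ValidationError(
            f"first column must be 'cpg_id', got {df.columns[0]!r}"
        )
    df = df.set_index("cpg_id")
    return df.astype(float)


def read_beta_matrix(path, dialect: str | None = None) -> BetaMatrix:
    """Read a CpG-by-sample beta matrix; empty cells become missing (NaN)."""
    return BetaMatrix(_read_matrix_frame(path, dialect))


def read_detection_p_matrix(path, dialect: str | None = None) -> DetectionPMatrix:
    return DetectionPMatrix(_read_matrix_frame(path, dialect))


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def read_cpg_annotation(path) -> CpGAnnotation:
    return CpGAnnotation(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name → set of gene symbols."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *genes = fields
            sets[name] = {g for g in genes if g}
    return sets


def read_normal_reference(path) -> pd.Series:
    """Read a normal-tissue reference (columns cpg_id, mean_beta)."""
    df = pd.read_csv(path)
    if not {"cpg_id", "mean_beta"} <= set(df.columns):
        raise ValidationError("normal reference needs columns cpg_id, mean_beta")
    s = df.set_index("cpg_id")["mean_beta"].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ValidationError("normal reference mean_beta outside [0, 1]")
    return s


def write_results_table(records, path) -> None:
    """Write a results table as a round-trippable CSV.

    Accepts a DataFrame or an iterable of homogeneous mappings.  Column
    order is the order of first appearance (deterministic); floats are
    written in shortest-round-trip form so ``read(write(x)) == x`` to full
    precision.  NaN serializes as an empty cell.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, index=False)
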