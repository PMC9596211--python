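"""Reading, validation and writing of cohort methylation tables and results.

A cohort table is a CSV/TSV with one row per sample: demographic columns
(``sample_id``, ``group``, ``sex``, ``age_at_collection``, optionally
``age_at_death``, ``oldest_parent_age_at_death``, ``oldest_parent_sex``,
``control_id``) followed by methylation percentages for the nine registry
CpGs.  Marker columns are matched case-insensitively against the registry.
Missing methylation cells are preserved as missing — never imputed; clocks
requiring a missing marker skip that sample downstream.

Result tables are written as TSV with a fixed column order, floats at four
decimals and a deterministic row order, so re-running a pipeline reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markers import MARKER_IDS

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "CohortTable",
    "LoadReport",
    "QCReport",
    "QCMarkerResult",
    "CohortValidationError",
    "InsufficientReplicatesError",
    "ResultsError",
    "read_cohort",
    "write_cohort",
    "qc_control_replicates",
    "write_results",
]

REQUIRED_COLUMNS = ("sample_id", "group", "sex", "age_at_collection")
OPTIONAL_COLUMNS = (
    "age_at_death",
    "oldest_parent_age_at_death",
    "oldest_parent_sex",
    "control_id",
)

DEFAULT_QC_TOLERANCE = 3.0  # percentage points; typical pyrosequencing technical SD


class CohortValidationError(ValueError):
    """The cohort table violates a structural or range constraint."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two control replicates were provided."""


class ResultsError(ValueError):
    """Result records are empty or of mixed kinds."""


@dataclass
class LoadReport:
    n_rows: int
    group_counts: dict[str, int]
    missing_methylation_cells: int


@dataclass
class CohortTable:
    """A validated cohort: demographics plus marker percentages (0-100)."""

    data: pd.DataFrame
    report: LoadReport | None = None

    @property
    def marker_columns(self) -> list[str]:
        return [m for m in MARKER_IDS if m in self.data.columns]

    def group(self, name: str) -> pd.DataFrame:
        return self.data[self.data["group"] == name]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        df = _validate_cohort_frame(df.copy())
        report = LoadReport(
            n_rows=len(df),
            group_counts=df["group"].value_counts().to_dict(),
            missing_methylation_cells=int(
                df[[m for m in MARKER_IDS if m in df.columns]].isna().sum().sum()
            ),
        )
        return cls(data=df, report=report)


def _validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort table lacks required column(s): {missing_cols}")
    df["sample_id"] = df["sample_id"].astype(str)
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if len(dupes):
        raise CohortValidationError(f"duplicate sample_id(s): {sorted(set(dupes))[:5]}")

    for col in ("age_at_collection", "age_at_death", "oldest_parent_age_at_death"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise CohortValidationError(f"unparseable value in column {col!r}: {exc}") from exc
    if (df["age_at_collection"] <= 0).any() or df["age_at_collection"].isna().any():
        bad = df.loc[~(df["age_at_collection"] > 0), "sample_id"].tolist()[:5]
        raise CohortValidationError(f"age_at_collection must be positive; bad sample(s): {bad}")
    if "age_at_death" in df.columns:
        both = df["age_at_death"].notna()
        if (df.loc[both, "age_at_death"] < df.loc[both, "age_at_collection"]).any():
            bad = df.loc[
                both & (df["age_at_death"] < df["age_at_collection"]), "sample_id"
            ].tolist()[:5]
            raise CohortValidationError(f"age_at_death < age_at_collection for sample(s): {bad}")

    for m in MARKER_IDS:
        if m not in df.columns:
            continue
        df[m] = pd.to_numeric(df[m])
        bad = df[m].notna() & ((df[m] < 0) | (df[m] > 100))
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise CohortValidationError(
                f"methylation outside [0, 100]: sample {row['sample_id']!r}, "
                f"column {m}, value {row[m]}"
            )
    return df


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError("dialect must be 'csv' or 'tsv'")
        return "," if dialect == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_cohort(path, dialect: str | None = None) -> CohortTable:
    """Read and validate a cohort table from CSV/TSV.

    Marker columns are matched case-insensitively and renamed to canonical
    registry ids; missing methylation stays missing (NaN).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, dialect), float_precision="round_trip")
    canon = {m.lower(): m for m in MARKER_IDS}
    df = df.rename(columns={c: canon[c.lower()] for c in df.columns if c.lower() in canon})
    return CohortTable.from_dataframe(df)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table (TSV or CSV by extension), full float precision."""
    path = Path(path)
    table.data.to_csv(path, sep=_infer_sep(path, None), index=False)


# ---------------------------------------------------------------------------
# control-replicate QC


@dataclass
class QCMarkerResult:
    marker_id: str
    mean_percent: float
    sd_percent: float
    passed: bool


@dataclass
class QCReport:
    """Per-marker between-replicate spread of a control DNA sample."""

    markers: list[QCMarkerResult]
    tolerance: float
    n_replicates: int

    @property
    def passed(self) -> bool:
        return all(m.passed for m in self.markers)


def qc_control_replicates(
    control_rows: CohortTable | pd.DataFrame,
    tolerance: float = DEFAULT_QC_TOLERANCE,
) -> QCReport:
    """Assess batch effects from replicate measurements of one control sample.

    The per-marker sample standard deviation (n-1 denominator) across
    replicates must stay within ``tolerance`` percentage points; a marker
    fails if SD > tolerance and the run passes only if every marker passes.
    """
    df = control_rows.data if isinstance(control_rows, CohortTable) else control_rows
    if len(df) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 control replicates, got {len(df)}"
        )
    results = []
    for m in MARKER_IDS:
        if m not in df.columns:
            continue
        vals = df[m].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise InsufficientReplicatesError(f"marker {m}: fewer than 2 replicate values")
        sd = float(np.std(vals, ddof=1))
        results.append(
            QCMarkerResult(
                marker_id=m,
                mean_percent=float(np.mean(vals)),
                sd_percent=sd,
                passed=sd <= tolerance,
            )
        )
    return QCReport(markers=results, tolerance=tolerance, n_replicates=len(df))


# ---------------------------------------------------------------------------
# result tables

_KIND_ORDERS: dict[str, tuple[list[str], list[str]]] = {
    # kind -> (canonical column order, sort keys)
    "predictions": (
        ["sample_id", "clock_name", "dnam_age", "age", "deviation", "extrapolated"],
        ["sample_id", "clock_name"],
    ),
    "contrasts": (
        [
            "group_a",
            "group_b",
            "clock_name",
            "mean_diff",
            "u_statistic",
            "p_two_tailed",
            "significant_at_0p05",
        ],
        ["group_a", "group_b", "clock_name"],
    ),
    "summary": (
        ["group", "clock_name", "n", "mean_deviation", "mad"],
        ["group", "clock_name"],
    ),
    "drift": (
        [
            "marker_id",
            "group_a",
            "group_b",
            "residual_sd_a",
            "residual_sd_b",
            "dispersion_ratio",
            "p_two_tailed",
            "drift_flagged",
        ],
        ["marker_id", "group_a", "group_b"],
    ),
    "correlations": (
        ["marker_id", "r", "p_two_sided", "n"],
        ["marker_id"],
    ),
}


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    recs = list(records)
    kinds = {type(r).__name__ for r in recs}
    if len(kinds) > 1:
        raise ResultsError(f"mixed record kinds: {sorted(kinds)}")
    rows = []
    for r in recs:
        d = dataclasses.asdict(r)
        d.pop("inputs_used", None)  # marker maps don't belong in flat tables
        rows.append(d)
    return pd.DataFrame(rows)


def write_results(records, path, kind: str) -> Path:
    """Write result records as a deterministic TSV.

    ``kind`` selects the column order and sort keys; floats are written at
    four decimals. Empty input is an error — never an empty file.
    """
    if kind not in _KIND_ORDERS:
        raise ResultsError(f"unknown result kind {kind!r}; choose from {sorted(_KIND_ORDERS)}")
    df = _records_to_frame(records)
    if df.empty:
        raise ResultsError("refusing to write an empty result table")
    order, sort_keys = _KIND_ORDERS[kind]
    cols = [c for c in order if c in df.columns] + [c for c in df.columns if c not in order]
    df = df[cols].sort_values([k for k in sort_keys if k in df.columns]).reset_index(drop=True)
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else _fmt_float(v))
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def _fmt_float(v: float) -> str:
    # keep tiny p-values legible instead of flushing them to 0.0000
    if v != 0 and abs(v) < 5e-5:
        return f"{v:.4e}"
    return f"{v:.4f}"
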