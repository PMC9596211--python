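"""Cohort statistics for DNAm-age deviations.

Core quantities:

* deviation = dnam_age - chronological age (years); negative means the
  subject is epigenetically *younger* than their chronological age;
* MAD = the arithmetic mean of |deviation| within a group (mean absolute
  deviation of DNAm age from chronological age — not the median-based
  robust MAD);
* two-group contrasts by the two-tailed Mann-Whitney U test at a fixed 0.05
  significance threshold, with no multiple-testing adjustment by default (a
  Benjamini-Hochberg helper is provided but opt-in);
* Pearson correlation of per-CpG methylation with age, two-sided p from the
  t transform with n-2 degrees of freedom.

The Mann-Whitney statistic is U = #{(i,j): a_i > b_j} + 0.5 * #{ties}.  For
combined samples of at most 16 values without ties the two-tailed p-value is
exact (full enumeration of the null rank distribution); otherwise the normal
approximation with tie and continuity corrections is used.  Ties always force
the corrected approximation, and p-values are floored at 1e-300. These
switch rules are fixed so results reproduce bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, stdtr

from .clocks import AgePrediction
from .io import CohortTable
from .markers import MARKER_IDS

__all__ = [
    "DeviationRecord",
    "GroupSummary",
    "Contrast",
    "CorrelationResult",
    "RegressionLine",
    "AnalysisError",
    "SingularFitError",
    "EXACT_MWU_MAX_N",
    "P_FLOOR",
    "SIGNIFICANCE_LEVEL",
    "compute_deviations",
    "deviations_frame",
    "mad",
    "pearson_r",
    "correlate_markers",
    "mann_whitney_u",
    "group_contrasts",
    "summarize_groups",
    "describe_cohort",
    "regression_line",
    "subgroup_compare",
    "benjamini_hochberg",
    "round_half_up",
]

#: Largest combined sample size for which the exact MWU null is enumerated.
EXACT_MWU_MAX_N = 16
#: Numerical floor for reported p-values.
P_FLOOR = 1e-300
#: Fixed two-sided significance threshold for all contrasts.
SIGNIFICANCE_LEVEL = 0.05


class AnalysisError(ValueError):
    """Invalid input to an analysis operation."""


class SingularFitError(AnalysisError):
    """A regression cannot be fitted (no age spread)."""


@dataclass(frozen=True)
class DeviationRecord:
    """Per-sample, per-clock DNAm age and its deviation from chronological age."""

    sample_id: str
    clock_name: str
    dnam_age: float
    age: float
    deviation: float  # dnam_age - age, years


@dataclass(frozen=True)
class GroupSummary:
    group: str
    clock_name: str
    n: int
    mean_deviation: float
    mad: float  # mean |deviation|, years


@dataclass(frozen=True)
class Contrast:
    """Two-group comparison of deviations under one clock."""

    group_a: str
    group_b: str
    clock_name: str
    mean_diff: float  # mean_dev_a - mean_dev_b, years
    u_statistic: float
    p_two_tailed: float
    significant_at_0p05: bool


@dataclass(frozen=True)
class CorrelationResult:
    marker_id: str
    r: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class RegressionLine:
    """OLS fit of deviation on chronological age within one group."""

    group: str
    clock_name: str
    slope: float  # years deviation per year of age
    intercept: float  # years


# ---------------------------------------------------------------------------
# deviations


def compute_deviations(
    predictions: Iterable[AgePrediction], cohort: CohortTable
) -> list[DeviationRecord]:
    """Join predictions to chronological ages; deviation = dnam_age - age."""
    ages = cohort.data.set_index("sample_id")["age_at_collection"]
    out = []
    for p in predictions:
        if p.sample_id not in ages.index:
            raise AnalysisError(f"prediction for unknown sample {p.sample_id!r}")
        age = float(ages.loc[p.sample_id])
        out.append(
            DeviationRecord(
                sample_id=p.sample_id,
                clock_name=p.clock_name,
                dnam_age=p.dnam_age,
                age=age,
                deviation=p.dnam_age - age,
            )
        )
    return out


def deviations_frame(records: Sequence[DeviationRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize deviation records to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "clock_name": [r.clock_name for r in records],
            "dnam_age": [r.dnam_age for r in records],
            "age": [r.age for r in records],
            "deviation": [r.deviation for r in records],
        }
    )


def mad(deviations: Sequence[float]) -> float:
    """Mean absolute deviation of DNAm age from chronological age (years)."""
    arr = np.asarray(deviations, dtype=float)
    if arr.size == 0:
        raise AnalysisError("mad of an empty list is undefined")
    return float(np.mean(np.abs(arr)))


# ---------------------------------------------------------------------------
# correlation


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R and two-sided p (t transform, n-2 df).

    Requires equal lengths, n >= 3 and non-zero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnalysisError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise AnalysisError("Pearson correlation needs n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = float(np.sqrt(np.sum(xd**2)))
    sy = float(np.sqrt(np.sum(yd**2)))
    if sx == 0.0 or sy == 0.0:
        raise AnalysisError("correlation undefined for a zero-variance variable")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, P_FLOOR
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stdtr(n - 2, -abs(t)))  # survival of |t| under t_{n-2}
    return r, max(p, P_FLOOR)


def correlate_markers(
    cohort: CohortTable, markers: Sequence[str] | None = None
) -> list[CorrelationResult]:
    """Per-CpG Pearson correlation of methylation with age over all samples."""
    markers = list(markers) if markers is not None else cohort.marker_columns
    out = []
    for m in markers:
        sub = cohort.data[["age_at_collection", m]].dropna()
        r, p = pearson_r(sub["age_at_collection"], sub[m])
        out.append(CorrelationResult(marker_id=m, r=r, p_two_sided=p, n=len(sub)))
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts over all C(n1+n2, n1) rank assignments.

    Built as the Gaussian binomial generating function
    prod_{i=1..n1} (1 - q^(n2+i)) / (1 - q^i); index u holds the number of
    assignments with exactly u a-over-b exceedances.
    """
    poly = np.array([1.0])
    for i in range(1, n1 + 1):
        factor = np.zeros(n2 + i + 1)
        factor[0], factor[n2 + i] = 1.0, -1.0
        poly = np.convolve(poly, factor)
        for j in range(i, len(poly)):  # exact division by (1 - q^i)
            poly[j] += poly[j - i]
    counts = np.zeros(n1 * n2 + 1)
    m = min(len(poly), n1 * n2 + 1)
    counts[:m] = poly[:m]
    return counts


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Returns (U, p) with U = #{(i,j): a_i > b_j} + 0.5 * #{ties}. Exact
    enumeration for tie-free inputs with n_a + n_b <= EXACT_MWU_MAX_N,
    otherwise normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise AnalysisError("Mann-Whitney requires non-empty samples")
    combined = np.concatenate([a, b])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty_like(combined)
    ranks[order] = np.arange(1, n1 + n2 + 1, dtype=float)
    # midranks for ties
    _, inv, cnt = np.unique(combined, return_inverse=True, return_counts=True)
    has_ties = bool((cnt > 1).any())
    if has_ties:
        cum = np.cumsum(cnt)
        mid = cum - (cnt - 1) / 2.0
        ranks = mid[inv]
    r1 = float(np.sum(ranks[:n1]))
    u = r1 - n1 * (n1 + 1) / 2.0

    if not has_ties and (n1 + n2) <= EXACT_MWU_MAX_N:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        k = int(round(u))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, max(p, P_FLOOR)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(cnt**3 - cnt)) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0  # all observations tied: no evidence either way
    # continuity correction toward the mean
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * float(ndtr(-z))
    return u, min(1.0, max(p, P_FLOOR))


# ---------------------------------------------------------------------------
# group machinery


def summarize_groups(
    devs: Sequence[DeviationRecord] | pd.DataFrame, cohort: CohortTable
) -> list[GroupSummary]:
    """Per (group, clock): n, mean deviation and MAD."""
    df = deviations_frame(devs).merge(
        cohort.data[["sample_id", "group"]], on="sample_id", how="left"
    )
    out = []
    for (g, c), sub in df.groupby(["group", "clock_name"], sort=True):
        out.append(
            GroupSummary(
                group=str(g),
                clock_name=str(c),
                n=len(sub),
                mean_deviation=float(sub["deviation"].mean()),
                mad=mad(sub["deviation"]),
            )
        )
    return out


def _contrast(dev_a: np.ndarray, dev_b: np.ndarray, ga: str, gb: str, clock: str) -> Contrast:
    u, p = mann_whitney_u(dev_a, dev_b)
    return Contrast(
        group_a=ga,
        group_b=gb,
        clock_name=clock,
        mean_diff=float(np.mean(dev_a) - np.mean(dev_b)),
        u_statistic=u,
        p_two_tailed=p,
        significant_at_0p05=p < SIGNIFICANCE_LEVEL,
    )


def group_contrasts(
    devs: Sequence[DeviationRecord] | pd.DataFrame,
    cohort: CohortTable,
    pairs: Sequence[tuple[str, str]],
    clocks: Sequence[str] | None = None,
) -> tuple[list[Contrast], dict[tuple[str, str], float]]:
    """Per-clock Mann-Whitney contrasts for each group pair, plus the
    clock-averaged mean difference per pair (the mean over clocks of the
    per-clock group-mean differences). No multiple-testing correction.
    """
    df = deviations_frame(devs).merge(
        cohort.data[["sample_id", "group"]], on="sample_id", how="left"
    )
    clock_names = sorted(df["clock_name"].unique()) if clocks is None else list(clocks)
    contrasts: list[Contrast] = []
    averages: dict[tuple[str, str], float] = {}
    for ga, gb in pairs:
        diffs = []
        for c in clock_names:
            da = df[(df["group"] == ga) & (df["clock_name"] == c)]["deviation"].to_numpy()
            db = df[(df["group"] == gb) & (df["clock_name"] == c)]["deviation"].to_numpy()
            if da.size == 0 or db.size == 0:
                empty = ga if da.size == 0 else gb
                raise AnalysisError(f"group {empty!r} has no deviations for clock {c!r}")
            res = _contrast(da, db, ga, gb, c)
            contrasts.append(res)
            diffs.append(res.mean_diff)
        averages[(ga, gb)] = float(np.mean(diffs))
    return contrasts, averages


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional helper; contrasts are unadjusted by default)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# descriptive table


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (report-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _msd_range(vals: pd.Series) -> dict[str, float]:
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def describe_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive statistics per group: n, age at collection / at death /
    oldest-parent age (mean, SD, range) and female count with one-decimal
    half-up percentage. Empty groups report n=0 and undefined percentages."""
    rows = []
    df = cohort.data
    for g, sub in df.groupby("group", sort=True):
        row: dict[str, object] = {"group": g, "n": len(sub)}
        if len(sub) == 0:
            rows.append(row)
            continue
        for col, prefix in (
            ("age_at_collection", "age"),
            ("age_at_death", "age_death"),
            ("oldest_parent_age_at_death", "parent_age"),
        ):
            if col in sub.columns and sub[col].notna().any():
                stats = _msd_range(sub[col].dropna())
                for k, v in stats.items():
                    row[f"{prefix}_{k}"] = v
        n_female = int((sub["sex"] == "F").sum())
        row["n_female"] = n_female
        pct = round_half_up(100.0 * n_female / len(sub), 1)
        row["pct_female"] = pct
        row["females_formatted"] = f"{n_female} ({pct:.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# regression of deviation on age


def regression_line(
    ages: Sequence[float],
    deviations: Sequence[float],
    group: str = "",
    clock_name: str = "",
) -> RegressionLine:
    """OLS of deviation on chronological age for one group and clock."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(deviations, dtype=float)
    if x.size < 2:
        raise AnalysisError("regression needs at least two points")
    if np.unique(x).size < 2:
        raise SingularFitError("all ages equal; deviation-vs-age line is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionLine(
        group=group, clock_name=clock_name, slope=float(slope), intercept=float(intercept)
    )


# ---------------------------------------------------------------------------
# subgroup comparisons

STRATIFICATIONS = (
    "sex_within_group",
    "nco_oldest_parent_age",
    "nco_oldest_parent_sex",
    "cssc_semisuper",
    "cssc_time_to_death",
)

SEMISUPER_AGE = 105.0  # years: centenarian vs semi-supercentenarian boundary
DEFAULT_TIME_TO_DEATH_K = 4.0  # years after collection


def subgroup_compare(
    cohort: CohortTable,
    devs: Sequence[DeviationRecord] | pd.DataFrame,
    stratification: str,
    k: float = DEFAULT_TIME_TO_DEATH_K,
    group: str | None = None,
) -> list[Contrast]:
    """Within-cohort stratified contrasts, same machinery as group_contrasts.

    Stratifications: sex within each group; NCO by oldest-parent longevity
    (centenarian >= 100 vs nonagenarian 90-99) or oldest-parent sex; CSSC
    semi-supercentenarian (age >= 105) vs centenarian; CSSC time to death
    (<= k vs > k years after collection).
    """
    if stratification not in STRATIFICATIONS:
        raise AnalysisError(
            f"unknown stratification {stratification!r}; choose from {STRATIFICATIONS}"
        )
    df = deviations_frame(devs).merge(cohort.data, on="sample_id", how="left")

    def _require(col: str) -> None:
        if col not in df.columns or df[col].isna().all():
            raise AnalysisError(f"stratification {stratification!r} requires column {col!r}")

    strata: list[tuple[str, pd.DataFrame, str, pd.DataFrame]] = []
    if stratification == "sex_within_group":
        groups = [group] if group else sorted(df["group"].dropna().unique())
        for g in groups:
            sub = df[df["group"] == g]
            strata.append((f"{g}:F", sub[sub["sex"] == "F"], f"{g}:M", sub[sub["sex"] == "M"]))
    elif stratification == "nco_oldest_parent_age":
        _require("oldest_parent_age_at_death")
        sub = df[df["group"] == (group or "NCO")]
        hi = sub[sub["oldest_parent_age_at_death"] >= 100.0]
        lo = sub[
            (sub["oldest_parent_age_at_death"] >= 90.0)
            & (sub["oldest_parent_age_at_death"] < 100.0)
        ]
        strata.append(("NCO:parent>=100", hi, "NCO:parent90-99", lo))
    elif stratification == "nco_oldest_parent_sex":
        _require("oldest_parent_sex")
        sub = df[df["group"] == (group or "NCO")]
        strata.append(
            (
                "NCO:parentF",
                sub[sub["oldest_parent_sex"] == "F"],
                "NCO:parentM",
                sub[sub["oldest_parent_sex"] == "M"],
            )
        )
    elif stratification == "cssc_semisuper":
        sub = df[df["group"] == (group or "CSSC")]
        strata.append(
            (
                "CSSC:>=105",
                sub[sub["age_at_collection"] >= SEMISUPER_AGE],
                "CSSC:<105",
                sub[sub["age_at_collection"] < SEMISUPER_AGE],
            )
        )
    else:  # cssc_time_to_death
        _require("age_at_death")
        sub = df[df["group"] == (group or "CSSC")].copy()
        ttd = sub["age_at_death"] - sub["age_at_collection"]
        strata.append(
            (f"CSSC:ttd<={k:g}", sub[ttd <= k], f"CSSC:ttd>{k:g}", sub[ttd > k])
        )

    out: list[Contrast] = []
    for name_a, sub_a, name_b, sub_b in strata:
        for c in sorted(df["clock_name"].dropna().unique()):
            da = sub_a[sub_a["clock_name"] == c]["deviation"].to_numpy()
            db = sub_b[sub_b["clock_name"] == c]["deviation"].to_numpy()
            if da.size == 0 or db.size == 0:
                empty = name_a if da.size == 0 else name_b
                raise AnalysisError(f"stratum {empty!r} is empty for clock {c!r}")
            out.append(_contrast(da, db, name_a, name_b, c))
    return out
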