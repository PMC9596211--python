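"""Quantifying epigenetic drift as excess within-group methylation dispersion.

Epigenetic drift — the stochastic, environment-driven divergence of
methylation between individuals — shows up at a CpG as *wider* scatter around
the age trend in very old groups, while clock-like CpGs stay tight.  To make
narrow-age extreme groups (e.g. centenarians spanning only 100-107 y)
comparable with wide-age reference groups, dispersion is measured on the
residuals of a *within-group* OLS fit of methylation on age, not about the
pooled trend.

The test is Brown-Forsythe-flavoured but rank-based: the median-centred
absolute residuals of the two groups are compared with the two-tailed
Mann-Whitney U test, and a marker is flagged as drifting only when the test
is significant at 0.05 AND the dispersion ratio (extreme / reference residual
SD) exceeds 1 — drift means *increased* dispersion, directionally.  This
quantitative formalization is this package's own; the underlying observation
it operationalizes is qualitative (scatter visible only at extreme ages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import SIGNIFICANCE_LEVEL, AnalysisError, mann_whitney_u
from .io import CohortTable

__all__ = ["DriftStat", "residual_dispersion", "drift_test", "classify_drift_markers"]


@dataclass(frozen=True)
class DriftStat:
    """Dispersion comparison of one marker between two groups."""

    marker_id: str
    group_a: str  # conventionally the extreme-age group
    group_b: str  # reference group
    residual_sd_a: float  # percent
    residual_sd_b: float  # percent
    dispersion_ratio: float  # sd_a / sd_b
    p_two_tailed: float
    drift_flagged: bool  # p < 0.05 and ratio > 1


def _group_residuals(cohort: CohortTable, marker: str, group: str) -> tuple[np.ndarray, int, bool]:
    """Within-group residuals of methylation about its own age trend.

    Returns (residuals, dof, mean_centered_fallback). Falls back to centering
    about the group mean when all ages coincide.
    """
    sub = cohort.data[cohort.data["group"] == group][["age_at_collection", marker]].dropna()
    n = len(sub)
    if n < 3:
        raise AnalysisError(
            f"group {group!r} has n={n} samples with marker {marker}; need >= 3"
        )
    ages = sub["age_at_collection"].to_numpy(dtype=float)
    meth = sub[marker].to_numpy(dtype=float)
    if np.unique(ages).size < 2:
        return meth - meth.mean(), n - 1, True
    slope, intercept = np.polyfit(ages, meth, 1)
    return meth - (intercept + slope * ages), n - 2, False


def residual_dispersion(cohort: CohortTable, marker: str, group: str) -> tuple[float, int]:
    """Residual SD of a marker about its within-group age trend.

    Uses an n-2 denominator (n-1 under the equal-ages mean-centred fallback).
    Returns (residual_sd percent, n).
    """
    resid, dof, _ = _group_residuals(cohort, marker, group)
    sd = float(np.sqrt(np.sum(resid**2) / dof))
    return sd, len(resid)


def drift_test(
    cohort: CohortTable, marker: str, group_a: str, group_b: str
) -> DriftStat:
    """Brown-Forsythe-style dispersion contrast of one marker between groups.

    Median-centred absolute residuals (about each group's own age trend) are
    compared with the two-tailed Mann-Whitney U test; ``group_a`` is
    conventionally the extreme-age group, and the marker is flagged only for
    significantly *increased* dispersion there (p < 0.05 and ratio > 1).
    """
    resid_a, dof_a, _ = _group_residuals(cohort, marker, group_a)
    resid_b, dof_b, _ = _group_residuals(cohort, marker, group_b)
    sd_a = float(np.sqrt(np.sum(resid_a**2) / dof_a))
    sd_b = float(np.sqrt(np.sum(resid_b**2) / dof_b))
    abs_a = np.abs(resid_a - np.median(resid_a))
    abs_b = np.abs(resid_b - np.median(resid_b))
    _, p = mann_whitney_u(abs_a, abs_b)
    ratio = sd_a / sd_b if sd_b > 0 else np.inf
    return DriftStat(
        marker_id=marker,
        group_a=group_a,
        group_b=group_b,
        residual_sd_a=sd_a,
        residual_sd_b=sd_b,
        dispersion_ratio=float(ratio),
        p_two_tailed=p,
        drift_flagged=bool(p < SIGNIFICANCE_LEVEL and ratio > 1.0),
    )


def classify_drift_markers(
    cohort: CohortTable,
    reference_group: str,
    extreme_group: str,
    markers: Sequence[str] | None = None,
) -> tuple[dict[str, bool], list[DriftStat]]:
    """Marker-wise drift classification of an extreme-age group vs reference.

    Returns (marker -> flag map, DriftStat list ranked by descending
    dispersion ratio).
    """
    markers = list(markers) if markers is not None else cohort.marker_columns
    stats = [drift_test(cohort, m, extreme_group, reference_group) for m in markers]
    stats.sort(key=lambda s: (-s.dispersion_ratio, s.marker_id))
    flags = {s.marker_id: s.drift_flagged for s in stats}
    return flags, stats
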