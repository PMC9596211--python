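"""Synthetic cohort generator emulating the study design of a three-group
blood methylation ageing cohort.

The generator produces, per sample, a chronological age drawn from its
group's distribution, an *epigenetic* age

    a* = a + delta_group + eta,        eta ~ Normal(0, individual_offset_sd^2)

(delta < 0 means the group is epigenetically younger), and per-marker
methylation

    m = clamp(alpha + beta * a* + eps, 0, 100),
    eps ~ Normal(0, (sigma0 + kappa * max(0, a - a0))^2)

so that baseline technical/biological noise (sigma0) is homoscedastic while
epigenetic drift adds linearly growing dispersion beyond an onset age a0 —
but only at the four drift-prone CpGs (kappa > 0 there, 0 elsewhere).

Default demographics mirror the studied cohorts: a general-population control
group (CG, n=149, ages 38-65), long-lived individuals' offspring (NCO, n=143,
ages 38-68) and centenarians/semi-supercentenarians (CSSC, n=214, ages
100-107), with the observed female fractions and group-level epigenetic-age
offsets of -2.3 y (NCO) and -15.8 y (CSSC) relative to CG.  Those offsets are
a *calibration* to the observed between-group contrasts, not a discovery of
the generator.

Randomness: one root seed; every sample consumes its own counter-derived
``SeedSequence`` stream, so adding or reordering groups never changes another
sample's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import calibrate_trajectories
from .clocks import builtin_regression_clocks, canonical_trajectories
from .io import CohortTable
from .markers import DRIFT_MARKERS, MARKER_IDS

__all__ = [
    "AgeDistribution",
    "TrajectoryParams",
    "GroupSpec",
    "SimConfig",
    "SimConfigError",
    "default_config",
    "default_trajectories",
    "simulate_cohort",
    "simulate_null_pair",
    "gaussian_deviations",
]

DEFAULT_SIGMA0 = 3.0  # baseline methylation noise SD, percentage points
DEFAULT_KAPPA = 0.06  # drift SD growth, percentage points per year past onset
DEFAULT_DRIFT_ONSET = 60.0  # years
DEFAULT_OFFSET_SD = 5.0  # between-subject biological-age SD, years


class SimConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass(frozen=True)
class AgeDistribution:
    """Uniform or truncated-normal age-at-collection distribution (years)."""

    kind: str  # "uniform" | "truncnorm"
    lo: float
    hi: float
    mu: float | None = None
    sigma: float | None = None

    def validate(self) -> None:
        if self.kind not in ("uniform", "truncnorm"):
            raise SimConfigError(f"unknown age distribution kind {self.kind!r}")
        if self.lo > self.hi:
            raise SimConfigError(f"age bounds inverted: [{self.lo}, {self.hi}]")
        if self.kind == "truncnorm" and (self.mu is None or self.sigma is None or self.sigma <= 0):
            raise SimConfigError("truncnorm requires mu and sigma > 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        for _ in range(10000):  # rejection sampling; bounds are wide in practice
            x = rng.normal(self.mu, self.sigma)
            if self.lo <= x <= self.hi:
                return float(x)
        return float(min(max(self.mu, self.lo), self.hi))


@dataclass(frozen=True)
class TrajectoryParams:
    """Linear mean trajectory and noise model of one marker."""

    alpha: float  # percent at age 0
    beta: float  # percent per year
    sigma0: float = DEFAULT_SIGMA0
    kappa: float = 0.0  # > 0 only for drift markers
    a0: float = DEFAULT_DRIFT_ONSET

    def validate(self, marker_id: str) -> None:
        if self.sigma0 < 0 or self.kappa < 0:
            raise SimConfigError(f"{marker_id}: sigma0 and kappa must be >= 0")

    def noise_sd(self, age: float) -> float:
        return self.sigma0 + self.kappa * max(0.0, age - self.a0)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, ages, epigenetic-age offset, sex mix."""

    name: str
    n: int
    age_distribution: AgeDistribution
    delta: float = 0.0  # group epigenetic-age offset, years (negative = younger)
    sex_female_fraction: float = 0.5
    time_to_death_mean: float | None = None  # exponential stub, years
    oldest_parent_age_distribution: AgeDistribution | None = None

    def validate(self) -> None:
        if self.n < 0:
            raise SimConfigError(f"group {self.name!r}: n must be >= 0")
        if not (0.0 <= self.sex_female_fraction <= 1.0):
            raise SimConfigError(f"group {self.name!r}: sex_female_fraction outside [0, 1]")
        self.age_distribution.validate()
        if self.oldest_parent_age_distribution is not None:
            self.oldest_parent_age_distribution.validate()
        if self.time_to_death_mean is not None and self.time_to_death_mean <= 0:
            raise SimConfigError(f"group {self.name!r}: time_to_death_mean must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Complete, reproducible description of one synthetic cohort."""

    seed: int
    groups: tuple[GroupSpec, ...]
    trajectories: dict[str, TrajectoryParams]
    individual_offset_sd: float = DEFAULT_OFFSET_SD

    def validate(self) -> None:
        if self.individual_offset_sd < 0:
            raise SimConfigError("individual_offset_sd must be >= 0")
        if not self.groups:
            raise SimConfigError("config defines no groups")
        for g in self.groups:
            g.validate()
        for m, t in self.trajectories.items():
            t.validate(m)


@lru_cache(maxsize=4)
def _calibrated_trajectories(age_lo: int, age_hi: int) -> tuple[tuple[str, float, float], ...]:
    # seed the inverse problem with the canonical trajectories the built-in
    # clocks (and the default GBR training recipe) were constructed from, so
    # the generator and the GBR clock agree on what methylation an age implies
    canon = {
        m: (t["alpha"], t["beta"]) for m, t in canonical_trajectories().items()
    }
    res = calibrate_trajectories(
        builtin_regression_clocks(),
        np.arange(age_lo, age_hi + 1),
        initial_trajectories=canon,
    )
    return tuple((m, a, b) for m, (a, b) in sorted(res.trajectories.items()))


def default_trajectories(
    sigma0: float = DEFAULT_SIGMA0,
    kappa: float = DEFAULT_KAPPA,
    drift_onset: float = DEFAULT_DRIFT_ONSET,
) -> dict[str, TrajectoryParams]:
    """Trajectories for all nine markers: calibrated against the built-in
    regression clocks where a marker enters a clock, canonical otherwise,
    with drift noise (kappa > 0) only on the four drift-prone CpGs."""
    calibrated = dict((m, (a, b)) for m, a, b in _calibrated_trajectories(38, 107))
    canon = canonical_trajectories()
    out: dict[str, TrajectoryParams] = {}
    for m in MARKER_IDS:
        alpha, beta = calibrated.get(m, (canon[m]["alpha"], canon[m]["beta"]))
        out[m] = TrajectoryParams(
            alpha=float(alpha),
            beta=float(beta),
            sigma0=sigma0,
            kappa=kappa if m in DRIFT_MARKERS else 0.0,
            a0=drift_onset,
        )
    return out


def default_config(
    seed: int = 0,
    delta_nco: float = -2.3,
    delta_cssc: float = -15.8,
    n_cg: int = 149,
    n_nco: int = 143,
    n_cssc: int = 214,
) -> SimConfig:
    """The study-condition configuration: observed group sizes, age
    distributions, sex mixes and calibrated group offsets."""
    groups = (
        GroupSpec(
            name="CG",
            n=n_cg,
            age_distribution=AgeDistribution("truncnorm", 38.0, 65.0, mu=56.0, sigma=4.7),
            delta=0.0,
            sex_female_fraction=0.383,
        ),
        GroupSpec(
            name="NCO",
            n=n_nco,
            age_distribution=AgeDistribution("truncnorm", 38.0, 68.0, mu=61.2, sigma=6.1),
            delta=delta_nco,
            sex_female_fraction=0.587,
            oldest_parent_age_distribution=AgeDistribution(
                "truncnorm", 90.0, 108.0, mu=96.8, sigma=3.1
            ),
        ),
        GroupSpec(
            name="CSSC",
            n=n_cssc,
            age_distribution=AgeDistribution("truncnorm", 100.0, 107.0, mu=101.3, sigma=1.4),
            delta=delta_cssc,
            sex_female_fraction=0.846,
            time_to_death_mean=2.0,
        ),
    )
    return SimConfig(seed=seed, groups=groups, trajectories=default_trajectories())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Draw a cohort table from a :class:`SimConfig` (bit-reproducible)."""
    config.validate()
    markers = [m for m in MARKER_IDS if m in config.trajectories]
    rows = []
    counter = 0
    root = int(config.seed)
    for gi, g in enumerate(config.groups):
        # deterministic female count; which samples are female is drawn from a
        # dedicated group-level stream so sample streams stay untouched
        n_female = _round_half_up(g.sex_female_fraction * g.n)
        grp_rng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(1_000_000 + gi,)))
        female_idx = set(grp_rng.permutation(g.n)[:n_female].tolist())
        for i in range(g.n):
            rng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(counter,)))
            counter += 1
            age = g.age_distribution.draw(rng)
            a_star = age + g.delta + rng.normal(0.0, config.individual_offset_sd)
            row: dict[str, object] = {
                "sample_id": f"{g.name}_{i:04d}",
                "group": g.name,
                "sex": "F" if i in female_idx else "M",
                "age_at_collection": age,
            }
            if g.time_to_death_mean is not None:
                row["age_at_death"] = age + rng.exponential(g.time_to_death_mean)
            if g.oldest_parent_age_distribution is not None:
                row["oldest_parent_age_at_death"] = g.oldest_parent_age_distribution.draw(rng)
                row["oldest_parent_sex"] = "F" if rng.random() < 0.5 else "M"
            eps = rng.standard_normal(len(markers))
            for k, m in enumerate(markers):
                t = config.trajectories[m]
                val = t.alpha + t.beta * a_star + eps[k] * t.noise_sd(age)
                row[m] = float(min(100.0, max(0.0, val)))
            rows.append(row)
    df = pd.DataFrame(rows)
    # stable column layout regardless of which optional fields any group used
    cols = ["sample_id", "group", "sex", "age_at_collection"]
    for c in ("age_at_death", "oldest_parent_age_at_death", "oldest_parent_sex"):
        if c in df.columns:
            cols.append(c)
    df = df[cols + markers]
    return CohortTable.from_dataframe(df)


def gaussian_deviations(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n Gaussian age deviations (years)."""
    if n < 2:
        raise SimConfigError("need n >= 2")
    if sd <= 0:
        raise SimConfigError("sd must be > 0")
    return rng.normal(mean, sd, size=n)


def simulate_null_pair(
    n1: int,
    n2: int,
    sd: float,
    seed: int,
    mean1: float = 0.0,
    mean2: float = 0.0,
    sd2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent Gaussian deviation samples under one seed.

    With the default zero means this is the null harness used to verify the
    contrast machinery's type-I error; non-zero means/SDs turn it into a
    two-group effect generator.
    """
    rng = np.random.default_rng(int(seed))
    a = gaussian_deviations(n1, mean1, sd, rng)
    b = gaussian_deviations(n2, mean2, sd if sd2 is None else sd2, rng)
    return a, b
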