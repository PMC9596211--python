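"""Deviation statistics: MAD, Pearson, Mann-Whitney (against scipy and
brute-force oracles), contrasts, descriptives, stratified comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cpgclock.analysis import (
    AnalysisError,
    P_FLOOR,
    SingularFitError,
    benjamini_hochberg,
    compute_deviations,
    correlate_markers,
    describe_cohort,
    group_contrasts,
    mad,
    mann_whitney_u,
    pearson_r,
    regression_line,
    round_half_up,
    subgroup_compare,
    summarize_groups,
)
from cpgclock.clocks import AgePrediction


def brute_force_mwu_p(a, b):
    """Exact two-tailed p by enumerating all rank assignments (tie-free)."""
    a, b = list(a), list(b)
    n1 = len(a)
    combined = sorted(a + b)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for positions in itertools.combinations(range(len(combined)), n1):
        sel = set(positions)
        av = [combined[i] for i in sel]
        bv = [combined[i] for i in range(len(combined)) if i not in sel]
        us.append(sum(1 for x in av for y in bv if x > y))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMad:
    def test_hand_example(self):
        assert mad([-3.0, 1.0, 2.0]) == pytest.approx(2.0)

    def test_sign_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 100)
        assert mad(x) == pytest.approx(mad(-x))

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            mad([])


class TestPearson:
    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        for n in (3, 5, 30, 200):
            for _ in range(20):
                x = rng.normal(size=n)
                y = 0.3 * x + rng.normal(size=n)
                r, p = pearson_r(x, y)
                ref = scipy.stats.pearsonr(x, y)
                assert r == pytest.approx(ref.statistic, abs=1e-12)
                assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_perfect_correlation_floors_p(self):
        # exactly representable sums: sum(xd^2) = 16, sqrt(16)^2 = 16
        x = [0.0, 0.0, 4.0, 4.0]
        r, p = pearson_r(x, x)
        assert r == 1.0 and p == P_FLOOR

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(AnalysisError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestMannWhitney:
    def test_u_statistic_definition(self):
        # a = {5, 1}, b = {2, 3}: exceedances (5>2, 5>3) = 2
        u, _ = mann_whitney_u([5.0, 1.0], [2.0, 3.0])
        assert u == 2.0

    def test_tie_counts_half(self):
        u, _ = mann_whitney_u([2.0], [2.0])
        assert u == 0.5

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(7)
        cases = 0
        while cases < 200:
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            vals = rng.normal(size=n1 + n2)
            if len(np.unique(vals)) < n1 + n2:
                continue
            a, b = vals[:n1], vals[n1:]
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)
            cases += 1

    def test_exact_branch_matches_scipy_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            if n1 + n2 > 16:
                continue
            a, b = rng.normal(size=n1), rng.normal(size=n2) + 0.5
            _, p = mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            a = rng.normal(size=60)
            b = rng.normal(size=45) + rng.uniform(-1, 1)
            _, p = mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_ties_match_scipy_asymptotic(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            a = rng.integers(0, 6, size=30).astype(float)
            b = rng.integers(0, 7, size=25).astype(float)
            _, p = mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=40), rng.normal(size=30) + 1.0
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(40 * 30)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_extreme_separation_floored_not_zero(self):
        a = np.linspace(0, 1, 400)
        b = np.linspace(100, 101, 400)
        _, p = mann_whitney_u(a, b)
        assert P_FLOOR <= p < 2.2e-16

    def test_all_tied_is_uninformative(self):
        u, p = mann_whitney_u([3.0] * 5, [3.0] * 7)
        assert p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_near_nominal(self):
        # 2000 null replicates at alpha=0.05: rejection rate within 3 SE
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            a, b = rng.normal(size=(2, 30))
            _, p = mann_whitney_u(a, b)
            rejections += p < 0.05
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestDeviations:
    def test_compute_deviations_sign_convention(self, tiny_cohort):
        preds = [AgePrediction("s1", "c", 35.0, {}, False)]
        (rec,) = compute_deviations(preds, tiny_cohort)
        assert rec.deviation == pytest.approx(-5.0)  # younger than 40 => negative

    def test_unknown_sample_rejected(self, tiny_cohort):
        with pytest.raises(AnalysisError):
            compute_deviations([AgePrediction("nope", "c", 35.0, {}, False)], tiny_cohort)


class TestGroupMachinery:
    def test_summaries_cover_all_group_clock_cells(self, default_cohort, default_deviations):
        summaries = summarize_groups(default_deviations, default_cohort)
        assert len(summaries) == 3 * 4
        by_key = {(s.group, s.clock_name): s for s in summaries}
        assert by_key[("CSSC", "Thong")].n == 214
        for s in summaries:
            assert s.mad >= abs(s.mean_deviation) - 1e-12

    def test_contrasts_shape_and_averages(self, default_cohort, default_deviations):
        pairs = [("NCO", "CG"), ("CSSC", "CG"), ("CSSC", "NCO")]
        contrasts, averages = group_contrasts(default_deviations, default_cohort, pairs)
        assert len(contrasts) == len(pairs) * 4
        for pair in pairs:
            per_clock = [
                c.mean_diff for c in contrasts if (c.group_a, c.group_b) == pair
            ]
            assert averages[pair] == pytest.approx(np.mean(per_clock))

    def test_cssc_vs_cg_strongly_significant(self, default_cohort, default_deviations):
        contrasts, _ = group_contrasts(
            default_deviations, default_cohort, [("CSSC", "CG")]
        )
        for c in contrasts:
            assert c.mean_diff < 0  # CSSC epigenetically younger
            assert c.significant_at_0p05

    def test_missing_group_rejected(self, default_cohort, default_deviations):
        with pytest.raises(AnalysisError, match="XX"):
            group_contrasts(default_deviations, default_cohort, [("XX", "CG")])

    def test_benjamini_hochberg_reference(self):
        # classical worked example
        p = [0.01, 0.04, 0.03, 0.005]
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDescriptives:
    def test_round_half_up_convention(self):
        assert round_half_up(84.55, 1) == 84.6
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(-1.5, 0) == -2.0  # half away from zero

    def test_describe_cohort_female_percentages(self, default_cohort):
        desc = describe_cohort(default_cohort)
        assert desc.loc["CSSC", "females_formatted"] == "181 (84.6%)"
        assert desc.loc["NCO", "females_formatted"] == "84 (58.7%)"
        assert desc.loc["CG", "females_formatted"] == "57 (38.3%)"

    def test_describe_cohort_age_stats(self, default_cohort):
        desc = describe_cohort(default_cohort)
        assert desc.loc["CSSC", "age_min"] >= 100.0
        assert desc.loc["CSSC", "age_max"] <= 107.0
        assert 95.0 <= desc.loc["NCO", "parent_age_mean"] <= 99.0
        assert desc.loc["CSSC", "age_death_mean"] > desc.loc["CSSC", "age_mean"]


class TestRegressionAndStrata:
    def test_regression_line_exact(self):
        line = regression_line([0.0, 1.0, 2.0], [1.0, 3.0, 5.0], group="g", clock_name="c")
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(1.0)

    def test_equal_ages_rejected(self):
        with pytest.raises(SingularFitError):
            regression_line([5.0, 5.0], [1.0, 2.0])

    def test_correlation_signs_on_default_cohort(self, default_cohort):
        res = {c.marker_id: c for c in correlate_markers(default_cohort)}
        assert res["ASPA_CpG1"].r < 0 and res["EDARADD_CpG1"].r < 0
        for m, c in res.items():
            if m not in ("ASPA_CpG1", "EDARADD_CpG1"):
                assert c.r > 0
            assert c.p_two_sided < 1e-10  # n=506 with strong age trends

    @pytest.mark.parametrize(
        "strat",
        [
            "sex_within_group",
            "nco_oldest_parent_age",
            "nco_oldest_parent_sex",
            "cssc_semisuper",
            "cssc_time_to_death",
        ],
    )
    def test_stratifications_run_on_default_cohort(
        self, strat, default_cohort, default_deviations
    ):
        out = subgroup_compare(default_cohort, default_deviations, strat)
        assert out and all(0.0 < c.p_two_tailed <= 1.0 for c in out)

    def test_unknown_stratification_rejected(self, default_cohort, default_deviations):
        with pytest.raises(AnalysisError, match="stratification"):
            subgroup_compare(default_cohort, default_deviations, "zodiac_sign")
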