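"""Compare epigenetic-age deviations between cohort groups.

Runs all four clocks over a simulated cohort, summarizes per-group mean
deviation and MAD, then tests every group pair with the two-tailed
Mann-Whitney U test and prints the clock-averaged deviation gaps.
"""

from cpgclock import (
    builtin_clocks,
    default_config,
    group_contrasts,
    simulate_cohort,
    summarize_groups,
)
from cpgclock.pipeline import predict_cohort

cohort = simulate_cohort(default_config(seed=42))
devs, _ = predict_cohort(cohort, builtin_clocks())

print("per-group summaries (deviation = DNAm age - age, years):")
for s in summarize_groups(devs, cohort):
    print(f"  {s.group:<5} {s.clock_name:<11} n={s.n:<4} "
          f"mean={s.mean_deviation:>7.2f}  MAD={s.mad:>6.2f}")

pairs = [("NCO", "CG"), ("CSSC", "CG"), ("CSSC", "NCO")]
contrasts, averages = group_contrasts(devs, cohort, pairs)

print("\nper-clock Mann-Whitney contrasts:")
for c in contrasts:
    star = "*" if c.significant_at_0p05 else " "
    print(f"  {c.group_a}-{c.group_b:<5} {c.clock_name:<11} "
          f"diff={c.mean_diff:>7.2f}  U={c.u_statistic:>9.1f}  "
          f"p={c.p_two_tailed:.3g} {star}")

print("\nclock-averaged deviation gaps (years):")
for (ga, gb), d in averages.items():
    print(f"  {ga} vs {gb}: {d:+.2f}")
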