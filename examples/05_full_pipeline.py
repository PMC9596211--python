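"""Run the full analysis pipeline end to end, with figures.

Simulates the default cohort, predicts DNAm ages with all clocks, writes
deterministic TSV tables (predictions, summaries, correlations, contrasts,
drift) and the standard figure set into ./pipeline_out.
"""

from pathlib import Path

from cpgclock import RunConfig, run_pipeline

outdir = run_pipeline(RunConfig(outdir="pipeline_out", seed=42, make_plots=True))

print(f"outputs in {outdir}/:")
for p in sorted(Path(outdir).iterdir()):
    print(f"  {p.name:<26}{p.stat().st_size:>9,d} bytes")

print("\nEquivalent shell command:")
print("  cpgclock analyze --seed 42 --out pipeline_out --plots")
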