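"""End-to-end pipeline: cohort in, predictions / statistics / figures out.

``run_pipeline`` chains the stages — read (or simulate) a cohort, optional
control-replicate QC, DNAm-age prediction with the selected clocks, per-sample
deviations, group summaries, per-CpG age correlations, Mann-Whitney group
contrasts, drift classification — and writes deterministic TSVs plus an
echoed config for provenance.  Any stage failure removes partial outputs and
re-raises as :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    compute_deviations,
    correlate_markers,
    deviations_frame,
    group_contrasts,
    regression_line,
    summarize_groups,
)
from .clocks import ClockModel, builtin_clocks, load_clock_definitions, predict_table
from .drift import classify_drift_markers
from .io import (
    CohortTable,
    qc_control_replicates,
    read_cohort,
    write_cohort,
    write_results,
)
from .simulate import default_config, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "predict_cohort", "make_figures"]

logger = logging.getLogger("cpgclock")

DEFAULT_PAIRS = (("NCO", "CG"), ("CSSC", "CG"), ("CSSC", "NCO"))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    outdir: str
    cohort_path: str | None = None  # None => simulate the default cohort
    seed: int = 0
    clock_file: str | None = None  # None => built-in registry
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    qc_tolerance: float | None = None  # run replicate QC when control rows exist
    drift_reference: str = "CG"
    drift_extreme: str = "CSSC"
    make_plots: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def predict_cohort(
    cohort: CohortTable, clocks: Sequence[ClockModel]
) -> tuple[pd.DataFrame, list[str]]:
    """All-clock predictions as a long table (sample_id, clock_name, dnam_age,
    age, deviation); samples missing a clock's markers are skipped for that
    clock and reported in the returned log."""
    idx = cohort.data.set_index("sample_id")
    frames, skipped = [], []
    for clock in clocks:
        pred = predict_table(clock, idx)
        missing = pred.index[pred.isna()]
        skipped += [f"clock {clock.name}: skipped sample {s} (missing marker)" for s in missing]
        ok = pred.dropna()
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ok.index,
                    "clock_name": clock.name,
                    "dnam_age": ok.to_numpy(),
                    "age": idx.loc[ok.index, "age_at_collection"].to_numpy(dtype=float),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["deviation"] = out["dnam_age"] - out["age"]
    return out, skipped


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("cpgclock %s, seed %d", __version__, config.seed)
        (outdir / "config.json").write_text(config.to_json())

        cohort = _load_cohort(config, outdir)
        clocks = _load_clocks(config)
        logger.info(
            "cohort: %d samples, groups %s", len(cohort.data), cohort.report.group_counts
        )

        if config.qc_tolerance is not None and "control_id" in cohort.data.columns:
            controls = cohort.data[cohort.data["control_id"].notna()]
            if len(controls) >= 2:
                qc = qc_control_replicates(controls, tolerance=config.qc_tolerance)
                logger.info("control QC: pass=%s", qc.passed)
                qc_df = pd.DataFrame([dataclasses.asdict(m) for m in qc.markers])
                qc_df.to_csv(outdir / "qc.tsv", sep="\t", index=False)

        devs, skipped = _predict(cohort, clocks)
        for line in skipped:
            logger.warning(line)
        write_results(devs, outdir / "predictions.tsv", kind="predictions")

        summaries = summarize_groups(devs, cohort)
        write_results(summaries, outdir / "summaries.tsv", kind="summary")
        write_results(correlate_markers(cohort), outdir / "correlations.tsv", kind="correlations")

        groups = set(cohort.data["group"].unique())
        pairs = [p for p in config.pairs if set(p) <= groups]
        contrasts, averages = (
            group_contrasts(devs, cohort, pairs) if pairs else ([], {})
        )
        if contrasts:
            write_results(contrasts, outdir / "contrasts.tsv", kind="contrasts")
            for (ga, gb), d in averages.items():
                logger.info("clock-averaged mean deviation difference %s-%s: %.2f y", ga, gb, d)

        if {config.drift_reference, config.drift_extreme} <= groups:
            _, drift_stats = classify_drift_markers(
                cohort, config.drift_reference, config.drift_extreme
            )
            write_results(drift_stats, outdir / "drift.tsv", kind="drift")

        if config.make_plots:
            make_figures(cohort, devs, outdir)
        return outdir
    except PipelineError:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


@_stage("read_cohort")
def _load_cohort(config: RunConfig, outdir: Path) -> CohortTable:
    if config.cohort_path is None:
        cohort = simulate_cohort(default_config(seed=config.seed))
        write_cohort(cohort, outdir / "simulated_cohort.tsv")
        return cohort
    return read_cohort(config.cohort_path)


@_stage("load_clocks")
def _load_clocks(config: RunConfig) -> list[ClockModel]:
    if config.clock_file is None:
        return builtin_clocks()
    return load_clock_definitions(config.clock_file)


@_stage("predict")
def _predict(cohort, clocks):
    return predict_cohort(cohort, clocks)


# ---------------------------------------------------------------------------
# figures


def make_figures(
    cohort: CohortTable,
    devs: pd.DataFrame | Sequence,
    outdir,
) -> list[Path]:
    """Standard figure set, with every plotted number also written as TSV.

    1. DNAm age vs chronological age per clock (with the y=x identity line);
    2. deviation vs age per clock with per-group regression lines;
    3. per-group deviation boxplots per clock, group means annotated;
    4. methylation vs age scatter per CpG.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = deviations_frame(devs).merge(
        cohort.data[["sample_id", "group"]], on="sample_id", how="left"
    )
    if df.empty:
        raise ValueError("no deviation records to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clock_names = sorted(df["clock_name"].unique())
    groups = sorted(df["group"].dropna().unique())
    colors = {g: c for g, c in zip(groups, plt.rcParams["axes.prop_cycle"].by_key()["color"])}
    paths: list[Path] = []

    def _grid(n):
        fig, axes = plt.subplots(1, n, figsize=(4.2 * n, 3.8), squeeze=False)
        return fig, axes[0]

    # 1 — DNAm age vs age
    fig, axes = _grid(len(clock_names))
    for ax, cname in zip(axes, clock_names):
        sub = df[df["clock_name"] == cname]
        for g in groups:
            gs = sub[sub["group"] == g]
            ax.scatter(gs["age"], gs["dnam_age"], s=6, alpha=0.5, label=g, color=colors[g])
        lims = [min(sub["age"].min(), sub["dnam_age"].min()), max(sub["age"].max(), sub["dnam_age"].max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set(title=cname, xlabel="chronological age (y)", ylabel="DNAm age (y)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "dnamage_vs_age.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # 2 — deviation vs age with group regression lines
    fig, axes = _grid(len(clock_names))
    for ax, cname in zip(axes, clock_names):
        sub = df[df["clock_name"] == cname]
        for g in groups:
            gs = sub[sub["group"] == g]
            ax.scatter(gs["age"], gs["deviation"], s=6, alpha=0.5, color=colors[g], label=g)
            if gs["age"].nunique() >= 2:
                line = regression_line(gs["age"], gs["deviation"], group=g, clock_name=cname)
                xs = np.array([gs["age"].min(), gs["age"].max()])
                ax.plot(xs, line.intercept + line.slope * xs, ":", color=colors[g])
        ax.axhline(0, color="k", lw=0.8)
        ax.set(title=cname, xlabel="chronological age (y)", ylabel="DNAm age - age (y)")
    fig.tight_layout()
    p = outdir / "deviation_vs_age.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # 3 — per-group deviation boxplots
    fig, axes = _grid(len(clock_names))
    for ax, cname in zip(axes, clock_names):
        sub = df[df["clock_name"] == cname]
        data = [sub[sub["group"] == g]["deviation"].to_numpy() for g in groups]
        ax.boxplot(data, tick_labels=groups)
        for i, d in enumerate(data, start=1):
            ax.annotate(f"{np.mean(d):.1f}", (i, np.min(d)), ha="center", va="top", fontsize=7)
        ax.set(title=cname, ylabel="DNAm age - age (y)")
    fig.tight_layout()
    p = outdir / "deviation_boxplots.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # 4 — methylation vs age per CpG
    markers = cohort.marker_columns
    if markers:
        fig, axes = plt.subplots(3, 3, figsize=(11, 9), squeeze=False)
        for ax, m in zip(axes.ravel(), markers):
            for g in groups:
                gs = cohort.data[cohort.data["group"] == g]
                ax.scatter(gs["age_at_collection"], gs[m], s=5, alpha=0.5, color=colors[g], label=g)
            ax.set(title=m, xlabel="age (y)", ylabel="methylation (%)")
        for ax in axes.ravel()[len(markers):]:
            ax.axis("off")
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        p = outdir / "methylation_vs_age.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    # figure data: the numbers behind every panel
    fig_data = df.sort_values(["sample_id", "clock_name"]).reset_index(drop=True)
    fig_data.to_csv(outdir / "figure_data.tsv", sep="\t", index=False)
    paths.append(outdir / "figure_data.tsv")
    return paths
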