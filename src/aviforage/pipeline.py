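"""End-to-end orchestration: simulate -> ingest -> kinematics -> model -> stats.

Every stage writes tidy CSV into the configured output directory and a
run manifest (config hash, seed, package version) so identical
configuration and seed reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .behavior_stats import lmm_lrt, rm_anova, rm_anova_within, summarize_ethogram
from .condition_model import BinnedSeries, Priors, fit_condition_model
from .config import RunConfig
from .errors import AviforageError, PipelineError
from .io import read_ethogram, read_manifest, read_trajectory
from .kinematics import session_stats
from .simulate import write_fixture_set

log = logging.getLogger("aviforage")

_FLOAT_FMT = "%.6g"


def run_pipeline(cfg: RunConfig) -> dict:
    """Run analyze + stats on an existing fixture/data set."""
    cfg.validate()
    out = _prepare_out(cfg)
    artifacts = {}
    artifacts.update(analyze(cfg))
    artifacts.update(stats(cfg))
    artifacts["run_manifest"] = str(_write_run_manifest(cfg))
    return artifacts


def simulate(cfg: RunConfig) -> dict:
    """Generate the synthetic fixture set configured under ``cfg.sim``."""
    from .config import SimConfig

    sim_cfg = cfg.sim or SimConfig(seed=cfg.seed)
    fixture_dir = Path(cfg.out_dir) / "fixtures"
    t0 = time.perf_counter()
    try:
        manifest = write_fixture_set(sim_cfg, fixture_dir)
    except (OSError, AviforageError) as exc:
        raise PipelineError("simulate", str(exc), path=str(fixture_dir)) from exc
    log.info("simulate: %d sessions in %.1fs", len(manifest), time.perf_counter() - t0)
    cfg.manifest = str(fixture_dir / "manifest.csv")
    cfg.ethogram = str(fixture_dir / "ethogram.csv")
    return {"fixtures": str(fixture_dir)}


def analyze(cfg: RunConfig) -> dict:
    """Ingest trajectories, compute per-session stats, fit the condition models."""
    cfg.validate()
    out = _prepare_out(cfg)
    t0 = time.perf_counter()
    try:
        manifest = read_manifest(cfg.manifest)
    except (OSError, AviforageError) as exc:
        raise PipelineError("ingest", str(exc), path=str(cfg.manifest)) from exc

    unknown = set(manifest["condition"]) - set(cfg.conditions)
    if unknown:
        raise PipelineError(
            "ingest",
            f"manifest contains conditions {sorted(unknown)} not in config",
            path=str(cfg.manifest),
        )

    base = Path(cfg.manifest).parent
    stat_rows = []
    session_bins = []
    bw = cfg.bin_width
    for row in manifest.itertuples():
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        try:
            traj = read_trajectory(path, fps=row.fps)
            st = session_stats(
                traj, cfg.arena, cfg.preprocessing, session_length=None
            )
        except AviforageError as exc:
            raise PipelineError("kinematics", str(exc), path=str(path)) from exc
        stat_rows.append(
            {
                "bird_id": row.bird_id,
                "condition": row.condition,
                "session": row.session,
                "latency_s": st.latency_s,
                "censored": st.censored,
                "log_activity": st.log_activity,
                "mean_orientation": st.mean_orientation,
            }
        )
        ori = st.orientation.dropna()
        b = (
            ori.groupby(np.floor(ori.index.to_numpy() / bw + 1e-7).astype(int))
            .agg(["mean", "size"])
            .reset_index(names="bin")
        )
        b["condition"] = row.condition
        b["bird_id"] = row.bird_id
        b["session"] = row.session
        session_bins.append(b)
    log.info(
        "kinematics: %d sessions in %.1fs", len(stat_rows), time.perf_counter() - t0
    )

    stats_df = pd.DataFrame(stat_rows)
    stats_path = out / "session_stats.csv"
    stats_df.to_csv(stats_path, index=False, float_format=_FLOAT_FMT)

    binned = _combine_session_bins(pd.concat(session_bins, ignore_index=True), bw)
    binned.values.to_csv(out / "binned_orientation.csv", float_format=_FLOAT_FMT)

    artifacts = {"session_stats": str(stats_path)}
    summaries = []
    for ref, alt in cfg.comparisons:
        t1 = time.perf_counter()
        try:
            res = fit_condition_model(
                binned,
                ref,
                alt,
                priors=Priors(),
                mcmc={
                    "draws": cfg.mcmc.draws,
                    "warmup": cfg.mcmc.warmup,
                    "chains": cfg.mcmc.chains,
                    "seed": cfg.seed,
                },
            )
        except AviforageError as exc:
            raise PipelineError("model", f"{ref}-{alt}: {exc}") from exc
        summaries.append(res.to_frame())
        tag = f"{ref}_{alt}"
        res.delta_bins().to_csv(
            out / f"delta_bins_{tag}.csv", index=False, float_format=_FLOAT_FMT
        )
        ax = res.plot()
        ax.figure.savefig(out / "plots" / f"difference_{tag}.png", dpi=120)
        plt.close(ax.figure)
        log.info("model %s-%s: %.1fs", ref, alt, time.perf_counter() - t1)
    posterior = pd.concat(summaries, ignore_index=True)
    posterior_path = out / "posterior_summary.csv"
    posterior.to_csv(posterior_path, index=False, float_format=_FLOAT_FMT)
    artifacts["posterior_summary"] = str(posterior_path)

    _plot_orientation(binned, out / "plots" / "orientation_timecourse.png")
    return artifacts


def stats(cfg: RunConfig) -> dict:
    """Ethogram summaries, RM-ANOVA, and mixed-model LRTs on session scalars."""
    cfg.validate()
    out = _prepare_out(cfg)
    try:
        etho = read_ethogram(cfg.ethogram)
    except (OSError, AviforageError) as exc:
        raise PipelineError("stats", str(exc), path=str(cfg.ethogram)) from exc

    summary = summarize_ethogram(etho)
    summary_path = out / "ethogram_summary.csv"
    summary.to_csv(summary_path, index=False, float_format=_FLOAT_FMT)

    test_frames = []
    posthoc_frames = []

    def collect(result):
        t = result.terms.copy()
        t.insert(0, "test", result.name)
        test_frames.append(t)
        if result.posthoc is not None:
            ph = result.posthoc.copy()
            ph.insert(0, "test", result.name)
            posthoc_frames.append(ph)

    try:
        collect(rm_anova(etho))
        for condition in cfg.conditions:
            collect(rm_anova_within(etho, condition))
    except AviforageError as exc:
        raise PipelineError("stats", f"rm_anova: {exc}") from exc

    stats_path = Path(cfg.out_dir) / "session_stats.csv"
    if stats_path.exists():
        sess = pd.read_csv(stats_path)
        for outcome in ("latency_s", "log_activity"):
            try:
                res = lmm_lrt(sess, outcome)
            except AviforageError as exc:
                raise PipelineError("stats", f"lmm[{outcome}]: {exc}") from exc
            collect(res)
        _plot_activity(sess, etho, Path(cfg.out_dir) / "plots" / "activity_behavior.png")

    tests_path = out / "behavior_tests.csv"
    pd.concat(test_frames, ignore_index=True).to_csv(
        tests_path, index=False, float_format=_FLOAT_FMT
    )
    artifacts = {"ethogram_summary": str(summary_path), "behavior_tests": str(tests_path)}
    if posthoc_frames:
        ph_path = out / "posthoc_tests.csv"
        pd.concat(posthoc_frames, ignore_index=True).to_csv(
            ph_path, index=False, float_format=_FLOAT_FMT
        )
        artifacts["posthoc_tests"] = str(ph_path)
    return artifacts


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _prepare_out(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    (out / "plots").mkdir(parents=True, exist_ok=True)
    return out


def _combine_session_bins(per_session: pd.DataFrame, bin_width: float) -> BinnedSeries:
    """Across-session averaging of per-session bin means (second binning stage)."""
    values = per_session.pivot_table(
        index="bin", columns="condition", values="mean", aggfunc="mean"
    )
    counts = (
        per_session.pivot_table(
            index="bin", columns="condition", values="size", aggfunc="sum"
        )
        .fillna(0)
        .astype(int)
    )
    full = np.arange(values.index.min(), values.index.max() + 1)
    values = values.reindex(full)
    counts = counts.reindex(full, fill_value=0)
    centers = (values.index.to_numpy() + 0.5) * bin_width
    values.index = pd.Index(centers, name="bin_time")
    counts.index = values.index
    return BinnedSeries(values=values, n_frames=counts, bin_width=bin_width)


def _write_run_manifest(cfg: RunConfig) -> Path:
    path = Path(cfg.out_dir) / "run_manifest.json"
    payload = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "aviforage_version": __version__,
        "comparisons": [list(c) for c in cfg.comparisons],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def _plot_orientation(binned: BinnedSeries, path: Path):
    fig, ax = plt.subplots(figsize=(8, 3))
    for cond in binned.values.columns:
        ax.plot(binned.bin_time, binned.values[cond], label=cond, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean orientation index")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_activity(sess: pd.DataFrame, etho: pd.DataFrame, path: Path):
    from .config import BODY_ORIENTED

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    order = list(dict.fromkeys(sess["condition"]))
    means = sess.groupby("condition")["log_activity"].agg(["mean", "sem"]).reindex(order)
    axes[0].bar(means.index, means["mean"], yerr=means["sem"], color="#9ecae1")
    axes[0].set_ylabel("log activity (log cm/s)")
    e = etho[(etho.get("rater", "R1") == "R1") & etho["behavior"].isin(BODY_ORIENTED)]
    counts = (
        e.groupby(["condition", "bird_id", "session"])["count"].sum().reset_index()
    )
    data = [counts.loc[counts["condition"] == c, "count"] for c in order]
    axes[1].boxplot(data, tick_labels=order)
    axes[1].set_ylabel("self-directed behaviors / session")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
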