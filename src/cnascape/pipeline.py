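"""End-to-end orchestration: simulate/load -> call -> frequency/arms ->
breakpoints -> hotspots -> ctlp -> cluster -> report."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breakpoint_hotspots as bh
from . import cna_calling as cc
from . import cohort_clustering as cl
from . import ctlp_scan as ct
from .genome_model import GenomeBuild, RegionSet, make_bins, toy_build
from .seg_io import Cohort, read_seg, write_run_summary, write_seg, write_table
from .synthetic_cohort import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_PARAMETERS"]

#: analysis defaults; every value mirrors the published parameter set
DEFAULT_PARAMETERS = {
    "gain_threshold": 0.2,
    "loss_threshold": -0.2,
    "breakpoint_delta": 0.4,
    "min_segment_size": 10_000,
    "bin_width": 1_000_000,
    "n_permutations": 10_000,
    "hotspot_alpha": 0.01,
    "ctlp_min_switches": 20,
    "ctlp_min_log10_lr": 10.0,
    "ctlp_min_diff": 0.4,
    "n_clusters": 2,
}


@dataclass
class RunConfig:
    """Shared configuration for a full pipeline run."""

    out_dir: str | Path = "cnascape_out"
    seg_path: str | Path | None = None  # None -> simulate
    build: GenomeBuild = field(default_factory=toy_build)
    sim: SimulationConfig | None = None
    cfs_path: str | Path | None = None
    nfr_path: str | Path | None = None
    seed: int = 0
    gain_threshold: float = DEFAULT_PARAMETERS["gain_threshold"]
    loss_threshold: float = DEFAULT_PARAMETERS["loss_threshold"]
    breakpoint_delta: float = DEFAULT_PARAMETERS["breakpoint_delta"]
    min_segment_size: int = DEFAULT_PARAMETERS["min_segment_size"]
    bin_width: int = DEFAULT_PARAMETERS["bin_width"]
    n_permutations: int = DEFAULT_PARAMETERS["n_permutations"]
    hotspot_alpha: float = DEFAULT_PARAMETERS["hotspot_alpha"]
    ctlp_min_switches: int = DEFAULT_PARAMETERS["ctlp_min_switches"]
    ctlp_min_log10_lr: float = DEFAULT_PARAMETERS["ctlp_min_log10_lr"]
    ctlp_min_diff: float = DEFAULT_PARAMETERS["ctlp_min_diff"]
    n_clusters: int = DEFAULT_PARAMETERS["n_clusters"]

    def parameters(self) -> dict:
        return {k: getattr(self, k) for k in DEFAULT_PARAMETERS}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; write tables + summary JSON.

    On a stage failure, partial outputs are retained next to a ``FAILED``
    marker naming the stage, and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"parameters": config.parameters(), "seed": config.seed,
                     "stages": {}}
    stage = "setup"
    try:
        stage = "input"
        if config.seg_path is not None:
            cohort = read_seg(config.seg_path, config.build)
        else:
            sim = config.sim or SimulationConfig(build=config.build, seed=config.seed)
            cohort, truth, clinical = simulate_cohort(sim, seed=config.seed)
            write_seg(cohort, out / "cohort.seg")
            clinical.df.to_csv(out / "clinical.tsv", sep="\t", index=False)
        grid = make_bins(cohort.build, config.bin_width)
        summary["stages"]["input"] = {
            "n_samples": cohort.n_samples, "n_segments": len(cohort.df),
            "n_bins": grid.n_bins,
        }

        stage = "call"
        calls = cc.call_states(cohort, config.gain_threshold, config.loss_threshold)
        write_table(calls, out / "calls.tsv")
        burden = cc.burden_summary(calls, cohort.build)
        write_table(burden, out / "burden.tsv")
        summary["stages"]["call"] = {
            "n_gain": int((calls["state"] == "gain").sum()),
            "n_loss": int((calls["state"] == "loss").sum()),
            "mean_events_per_sample": float(burden["n_events"].mean()),
        }

        stage = "frequency"
        profile = cc.frequency_profile(calls, grid)
        write_table(profile, out / "frequency.tsv")
        summary["stages"]["frequency"] = {
            "max_gain_freq": float(profile["gain_freq"].max()),
            "max_loss_freq": float(profile["loss_freq"].max()),
        }

        stage = "arms"
        arm_events = cc.call_arm_events(calls, cohort.build)
        write_table(arm_events, out / "arm_events.tsv")
        r, p = cc.arm_gain_loss_correlation(arm_events, cohort.n_samples, cohort.build)
        summary["stages"]["arms"] = {
            "n_arm_events": len(arm_events),
            "gain_loss_correlation_r": None if np.isnan(r) else r,
            "gain_loss_correlation_p": None if np.isnan(p) else p,
        }

        stage = "breakpoints"
        bps = bh.extract_breakpoints(
            cohort, config.breakpoint_delta, config.min_segment_size
        )
        write_table(bps, out / "breakpoints.tsv")
        summary["stages"]["breakpoints"] = {
            "n_breakpoints": len(bps),
            "mean_per_sample": len(bps) / cohort.n_samples,
        }

        stage = "hotspots"
        observed = bh.count_per_bin(bps, grid)
        null = bh.permute_breakpoints(
            bps, cohort.build, grid, n_perm=config.n_permutations, seed=config.seed
        )
        hotspots = bh.hotspot_test(observed, null, grid, alpha=config.hotspot_alpha)
        for which, path in (("cfs", config.cfs_path), ("nfr", config.nfr_path)):
            if path is not None:
                rs = RegionSet.from_bed(path, label=which.upper(), build=cohort.build)
                hotspots = bh.annotate_overlap(hotspots, rs)
        write_table(hotspots, out / "hotspots.tsv")
        summary["stages"]["hotspots"] = {
            "n_hotspots": int(hotspots["is_hotspot"].sum()),
            "n_permutations": config.n_permutations,
        }

        stage = "ctlp"
        ctlp = ct.scan_cohort(
            cohort,
            switch_thr=config.ctlp_min_switches,
            lr_thr=config.ctlp_min_log10_lr,
            min_seg=config.min_segment_size,
            diff_thr=config.ctlp_min_diff,
            gain_thr=config.gain_threshold,
            loss_thr=config.loss_threshold,
        )
        write_table(ctlp, out / "ctlp.tsv")
        ctlp_summary = ct.summarize_ctlp(ctlp, cohort.n_samples)
        summary["stages"]["ctlp"] = {
            "n_cases": ctlp_summary.n_positive,
            "incidence": ctlp_summary.incidence,
        }

        stage = "cluster"
        matrix = cl.build_matrix(calls, grid, mode="state")
        assignment = cl.ward_cluster(matrix, k=config.n_clusters)
        assign_df = assignment.labels.rename_axis("sample").reset_index()
        write_table(assign_df, out / "clusters.tsv")
        write_table(
            pd.DataFrame(
                assignment.linkage,
                columns=["left", "right", "height", "n_members"],
            ),
            out / "linkage.tsv",
        )
        csum = cl.cluster_summary(assignment, calls, arm_events, cohort.build)
        write_table(csum, out / "cluster_summary.tsv")
        summary["stages"]["cluster"] = {
            "k": config.n_clusters,
            "sizes": csum["n_samples"].tolist(),
        }
    except Exception as exc:  # noqa: BLE001 - report stage then re-raise
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    summary["wall_time_s"] = round(time.time() - t0, 3)
    write_run_summary(out / "run_summary.json", **summary)
    return summary
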