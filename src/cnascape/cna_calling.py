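"""CNA state calling, frequency profiles, burden and arm-level events.

Gain/loss states are called on segment log2 ratios with strict thresholds
(log2 > 0.2 gain, log2 < -0.2 loss, else neutral).  Frequencies are
computed on a fixed bin grid: within one sample a bin takes the state
whose segments cover the largest fraction of the bin, provided that state
covers more than half the bin; ties or insufficient coverage leave the bin
neutral, so per bin gain_freq + loss_freq <= 1 by construction.

An arm-level event is a (merged) run of same-state segments covering more
than 50% of a chromosome arm.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import BinGrid, GenomeBuild
from .seg_io import Cohort

__all__ = [
    "call_states",
    "burden_summary",
    "sample_bin_states",
    "frequency_profile",
    "call_arm_events",
    "arm_frequencies",
    "arm_gain_loss_correlation",
]

GAIN_THR = 0.2
LOSS_THR = -0.2

STATE_CODE = {"gain": 1, "neutral": 0, "loss": -1}


def call_states(
    cohort: Cohort, gain_thr: float = GAIN_THR, loss_thr: float = LOSS_THR
) -> pd.DataFrame:
    """Assign one state per segment: gain (log2 > gain_thr), loss
    (log2 < loss_thr) or neutral.  Thresholds are strict, so boundary
    values are neutral.

    Returns the cohort frame with an added ``state`` column.
    """
    if not (loss_thr < 0 < gain_thr):
        raise ValueError(
            f"thresholds must satisfy loss_thr < 0 < gain_thr, "
            f"got ({gain_thr}, {loss_thr})"
        )
    calls = cohort.df.copy()
    log2 = calls["log2"].to_numpy()
    state = np.where(log2 > gain_thr, "gain", np.where(log2 < loss_thr, "loss", "neutral"))
    calls["state"] = state
    return calls


def burden_summary(calls: pd.DataFrame, build: GenomeBuild) -> pd.DataFrame:
    """Per-sample CNA burden: event count, mean event size, genome fraction.

    An *event* is one non-neutral called segment.  Mean size is NaN for
    all-neutral samples; the altered genome fraction uses the build's total
    autosome length as denominator.
    """
    calls = calls.copy()
    calls["_len"] = calls["end"] - calls["start"]
    alt = calls[calls["state"] != "neutral"]
    grouped = alt.groupby("sample")["_len"]
    out = pd.DataFrame({"sample": sorted(calls["sample"].unique())})
    n = grouped.count()
    size = grouped.mean()
    total = grouped.sum()
    out["n_events"] = out["sample"].map(n).fillna(0).astype(int)
    out["mean_event_size"] = out["sample"].map(size)
    out["fraction_genome_altered"] = (
        out["sample"].map(total).fillna(0.0) / build.total_length
    )
    return out


def _coverage_by_state(
    sample_df: pd.DataFrame, grid: BinGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin bp covered by gain and by loss segments of one sample."""
    gain_cov = np.zeros(grid.n_bins, dtype=np.int64)
    loss_cov = np.zeros(grid.n_bins, dtype=np.int64)
    w = grid.width
    sub = sample_df[sample_df["state"] != "neutral"]
    for chrom, s, e, state in zip(sub["chrom"], sub["start"], sub["end"], sub["state"]):
        cov = gain_cov if state == "gain" else loss_cov
        off = grid.offsets[chrom]
        first, last = s // w, (e - 1) // w
        if first == last:
            cov[off + first] += e - s
        else:
            cov[off + first] += (first + 1) * w - s
            cov[off + last] += e - last * w
            if last > first + 1:
                cov[off + first + 1 : off + last] += w
    return gain_cov, loss_cov


def sample_bin_states(sample_df: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    """Collapse one sample's segment calls to one state per bin.

    A bin is gain (+1) or loss (-1) when that state covers the largest
    fraction of the bin AND more than half of it; ties or <=50% coverage
    give neutral (0).
    """
    gain_cov, loss_cov = _coverage_by_state(sample_df, grid)
    half = grid.lengths / 2.0
    out = np.zeros(grid.n_bins, dtype=np.int8)
    out[(gain_cov > loss_cov) & (gain_cov > half)] = 1
    out[(loss_cov > gain_cov) & (loss_cov > half)] = -1
    return out


def frequency_profile(calls: pd.DataFrame, grid: BinGrid) -> pd.DataFrame:
    """Genome-wide gain/loss frequency per bin across the cohort."""
    samples = sorted(calls["sample"].unique())
    gain_n = np.zeros(grid.n_bins, dtype=np.int64)
    loss_n = np.zeros(grid.n_bins, dtype=np.int64)
    for _, sub in calls.groupby("sample", sort=False):
        st = sample_bin_states(sub, grid)
        gain_n += st == 1
        loss_n += st == -1
    out = grid.df.copy()
    out["gain_freq"] = gain_n / len(samples)
    out["loss_freq"] = loss_n / len(samples)
    out["n_samples"] = len(samples)
    return out


def _state_runs(sub: pd.DataFrame, merge_adjacent: bool) -> Iterable[pd.DataFrame]:
    """Maximal runs of consecutive same-state non-neutral segments."""
    states = sub["state"].to_numpy()
    run_id = np.cumsum(np.r_[True, states[1:] != states[:-1]])
    if not merge_adjacent:
        run_id = np.arange(len(sub))
    for _, run in sub.groupby(run_id, sort=False):
        if run["state"].iloc[0] != "neutral":
            yield run


def call_arm_events(
    calls: pd.DataFrame,
    build: GenomeBuild,
    merge_adjacent: bool = True,
) -> pd.DataFrame:
    """Arm-level events: a run of same-state segments covering >50% of an arm.

    Adjacent same-state segments are merged into runs first (segmentation
    splits single biological events); ``merge_adjacent=False`` restricts to
    literal single segments.  Per sample and arm, at most one gain and one
    loss event is reported (the largest run of each state).  The covered
    fraction sums segment overlaps with the arm, so gaps inside a run do
    not count.  Arm-less chromosomes are skipped.
    """
    arms = list(build.arm_intervals())
    rows: list[tuple[str, str, str, float]] = []
    for (sample, chrom), sub in calls.groupby(["sample", "chrom"], sort=False):
        chrom_arms = [(lab, s, e) for lab, c, s, e in arms if c == chrom]
        if not chrom_arms:
            continue
        for run in _state_runs(sub, merge_adjacent):
            state = run["state"].iloc[0]
            starts = run["start"].to_numpy()
            ends = run["end"].to_numpy()
            for label, a_s, a_e in chrom_arms:
                covered = np.maximum(
                    0, np.minimum(ends, a_e) - np.maximum(starts, a_s)
                ).sum()
                frac = covered / (a_e - a_s)
                if frac > 0.5:
                    rows.append((sample, label, state, float(frac)))
    out = pd.DataFrame(rows, columns=["sample", "arm", "type", "covered_fraction"])
    if out.empty:
        return out
    # keep the largest run per sample+arm+state
    out = (
        out.sort_values("covered_fraction", ascending=False)
        .drop_duplicates(["sample", "arm", "type"])
        .sort_values(["sample", "arm", "type"])
        .reset_index(drop=True)
    )
    return out


def arm_frequencies(
    arm_events: pd.DataFrame, n_samples: int, build: GenomeBuild
) -> pd.DataFrame:
    """Per-arm gain and loss event frequency across the cohort."""
    rows = []
    for label in build.arm_labels:
        sub = arm_events[arm_events["arm"] == label] if len(arm_events) else arm_events
        gain = sub[sub["type"] == "gain"]["sample"].nunique() if len(sub) else 0
        loss = sub[sub["type"] == "loss"]["sample"].nunique() if len(sub) else 0
        rows.append((label, gain / n_samples, loss / n_samples))
    return pd.DataFrame(rows, columns=["arm", "gain_freq", "loss_freq"])


def arm_gain_loss_correlation(
    arm_events: pd.DataFrame, n_samples: int, build: GenomeBuild
) -> tuple[float, float]:
    """Pearson correlation between arm-level gain and loss frequencies.

    Computed across arms; two-sided p from the t-distribution.  Returns
    ``(nan, nan)`` with a warning when either frequency vector has zero
    variance.
    """
    freqs = arm_frequencies(arm_events, n_samples, build)
    if len(freqs) < 3:
        raise ValueError("need >= 3 arms with defined frequencies")
    g = freqs["gain_freq"].to_numpy()
    l = freqs["loss_freq"].to_numpy()
    if np.ptp(g) == 0 or np.ptp(l) == 0:
        warnings.warn(
            "zero variance in arm gain or loss frequencies; "
            "correlation undefined",
            stacklevel=2,
        )
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(g, l)
    return (float(r), float(p))
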