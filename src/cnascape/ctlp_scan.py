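"""Chromothripsis-like pattern (CTLP) detection on segmented profiles.

On array-level data chromothripsis shows as many clustered oscillations of
the copy-number state along one chromosome.  A candidate region qualifies
when it passes all four thresholds jointly: copy-number status switches
>= 20, log10 clustering likelihood ratio >= 10, minimum retained segment
size 10 kb, and adjacent-segment signal difference >= 0.4.

A *switch* is a pair of consecutive retained segments whose call states
differ AND whose |log2 difference| meets the difference threshold (the two
conditions jointly guard against both slow drifts and sub-threshold
flicker).

The clustering likelihood ratio compares a two-rate Poisson model of
switch positions (rate ``k/L`` inside the candidate region, ``(N-k)/(G-L)``
outside) against a homogeneous model (rate ``N/G`` everywhere).  It is 0
under homogeneity and strictly increasing in the degree of clustering;
when every switch on the chromosome lies in the region it reduces to
``N * ln(G/L) / ln(10)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna_calling import GAIN_THR, LOSS_THR
from .genome_model import GenomeBuild
from .seg_io import Cohort

__all__ = [
    "count_status_switches",
    "switch_positions",
    "clustering_lr",
    "scan_chromosome",
    "scan_cohort",
    "CTLPSummary",
    "summarize_ctlp",
]

MIN_SEG = 10_000
DIFF_THR = 0.4
SWITCH_THR = 20
LR_THR = 10.0
WINDOW = 30_000_000
STEP = 5_000_000


def _states(log2: np.ndarray, gain_thr: float, loss_thr: float) -> np.ndarray:
    return np.where(log2 > gain_thr, 1, np.where(log2 < loss_thr, -1, 0))


def switch_positions(
    segments: pd.DataFrame,
    min_seg: int = MIN_SEG,
    diff_thr: float = DIFF_THR,
    gain_thr: float = GAIN_THR,
    loss_thr: float = LOSS_THR,
) -> np.ndarray:
    """Positions of copy-number status switches on one chromosome.

    Segments shorter than ``min_seg`` are dropped first; a switch is a
    boundary between consecutive retained segments with differing call
    states and |delta log2| >= ``diff_thr``.  The position is the left
    segment end (midpoint of the gap for non-abutting segments).
    """
    lens = (segments["end"] - segments["start"]).to_numpy()
    kept = segments[lens >= min_seg]
    if len(kept) < 2:
        return np.empty(0, dtype=np.int64)
    log2 = kept["log2"].to_numpy()
    st = _states(log2, gain_thr, loss_thr)
    delta = np.abs(np.diff(log2))
    is_switch = (np.diff(st) != 0) & (delta >= diff_thr)
    ends = kept["end"].to_numpy()[:-1]
    starts = kept["start"].to_numpy()[1:]
    pos = np.where(starts <= ends, ends, (ends + starts) // 2)
    return pos[is_switch].astype(np.int64)


def count_status_switches(
    segments: pd.DataFrame,
    min_seg: int = MIN_SEG,
    diff_thr: float = DIFF_THR,
    gain_thr: float = GAIN_THR,
    loss_thr: float = LOSS_THR,
) -> int:
    """Number of copy-number status switches on one chromosome."""
    return int(
        switch_positions(segments, min_seg, diff_thr, gain_thr, loss_thr).size
    )


def clustering_lr(k: int, L: float, N: int, G: float) -> float:
    """log10 likelihood ratio for ``k`` of ``N`` events clustering in a
    region of length ``L`` on a chromosome of length ``G``.

    Two-rate Poisson clustered model versus homogeneous model; 0 when
    ``k == 0`` or the inside rate equals the genome-wide rate.
    """
    if L <= 0 or G <= 0:
        raise ValueError(f"lengths must be positive, got L={L}, G={G}")
    if k < 0 or N < k:
        raise ValueError(f"need 0 <= k <= N, got k={k}, N={N}")
    if k == 0 or N == 0:
        return 0.0
    lam1 = k / L
    lam0 = N / G
    if lam1 == lam0:
        return 0.0
    ll = k * math.log(lam1 / lam0) - (lam1 - lam0) * L
    rest = N - k
    if G > L:
        lam2 = rest / (G - L)
        if rest > 0:
            ll += rest * math.log(lam2 / lam0)
        ll -= (lam2 - lam0) * (G - L)
    return ll / math.log(10)


def _window_grid(chrom_len: int, window: int, step: int) -> list[tuple[int, int]]:
    """Multi-scale sliding windows: sizes grow x1.5 from ``window`` up to
    the chromosome length; each size slides by ``step`` with a flush-right
    final placement."""
    sizes = []
    w = window
    while w < chrom_len:
        sizes.append(int(w))
        w = int(w * 1.5)
    sizes.append(chrom_len)
    out = []
    for w in sizes:
        starts = list(range(0, max(chrom_len - w, 0) + 1, step))
        if starts[-1] != chrom_len - w:
            starts.append(chrom_len - w)
        for s in starts:
            out.append((s, s + w))
    return out


def scan_chromosome(
    segments: pd.DataFrame,
    chrom_len: int,
    window: int = WINDOW,
    step: int = STEP,
    switch_thr: int = SWITCH_THR,
    lr_thr: float = LR_THR,
    min_seg: int = MIN_SEG,
    diff_thr: float = DIFF_THR,
    gain_thr: float = GAIN_THR,
    loss_thr: float = LOSS_THR,
) -> list[dict]:
    """Scan one sample chromosome for chromothripsis-like regions.

    Sliding multi-scale windows are screened for ``switch_thr`` switches;
    a window's LR is evaluated on the span of the switches it contains
    (window placement then only decides which switches cluster together,
    avoiding window-length bias).  Overlapping qualifying spans are merged
    and each merged region is re-evaluated once on its own switch span.
    Returns a list of dicts with ``start``, ``end``, ``n_switches``,
    ``log10_lr``, ``is_ctlp``.
    """
    if window <= 0 or step <= 0 or switch_thr <= 0:
        raise ValueError("window, step and switch_thr must be positive")
    pos = switch_positions(segments, min_seg, diff_thr, gain_thr, loss_thr)
    N = pos.size
    if N < switch_thr:
        return []

    spans: list[tuple[int, int]] = []
    for ws, we in _window_grid(chrom_len, min(window, chrom_len), step):
        inside = pos[(pos >= ws) & (pos < we)]
        k = inside.size
        if k < switch_thr:
            continue
        span_s, span_e = int(inside[0]), int(inside[-1])
        L = max(span_e - span_s, 1)
        if clustering_lr(k, L, N, chrom_len) >= lr_thr:
            spans.append((span_s, span_e))
    if not spans:
        return []

    spans.sort()
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    results = []
    for s, e in merged:
        inside = pos[(pos >= s) & (pos <= e)]
        k = inside.size
        L = max(e - s, 1)
        lr = clustering_lr(k, L, N, chrom_len)
        results.append(
            {
                "start": int(s),
                "end": int(e),
                "n_switches": int(k),
                "log10_lr": float(lr),
                "is_ctlp": bool(k >= switch_thr and lr >= lr_thr),
            }
        )
    return results


def scan_cohort(cohort: Cohort, **params) -> pd.DataFrame:
    """Run :func:`scan_chromosome` over every sample chromosome.

    Returns a frame with columns ``sample``, ``chrom``, ``start``, ``end``,
    ``n_switches``, ``log10_lr``, ``is_ctlp``.
    """
    rows = []
    build = cohort.build
    for (sample, chrom), sub in cohort.sample_chrom_groups():
        for hit in scan_chromosome(sub, build.length(chrom), **params):
            rows.append({"sample": sample, "chrom": chrom, **hit})
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "n_switches", "log10_lr", "is_ctlp"],
    )


@dataclass(frozen=True)
class CTLPSummary:
    """Cohort-level chromothripsis-like pattern summary."""

    n_samples: int
    n_positive: int
    incidence: float
    per_chrom: pd.DataFrame  # chrom, n_cases, fraction (of positive samples)
    per_sample: pd.DataFrame  # sample, n_chromosomes
    multi_chromosome_fraction: float  # positives with >= 2 affected chromosomes


def summarize_ctlp(results: pd.DataFrame, n_samples: int) -> CTLPSummary:
    """Summarize CTLP calls: incidence, per-chromosome shares, multiplicity.

    A sample is a chromothripsis case if >= 1 chromosome qualifies.
    Per-chromosome fractions use CTLP-positive samples as denominator and
    attribute one count per qualifying sample chromosome.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    pos = results[results["is_ctlp"]] if len(results) else results
    positive_samples = sorted(pos["sample"].unique()) if len(pos) else []
    n_pos = len(positive_samples)
    if n_pos:
        sample_chrom = pos[["sample", "chrom"]].drop_duplicates()
        per_chrom = (
            sample_chrom.groupby("chrom").size().rename("n_cases").reset_index()
        )
        per_chrom["fraction"] = per_chrom["n_cases"] / n_pos
        per_chrom = per_chrom.sort_values("n_cases", ascending=False).reset_index(
            drop=True
        )
        per_sample = (
            sample_chrom.groupby("sample").size().rename("n_chromosomes").reset_index()
        )
        multi = float((per_sample["n_chromosomes"] >= 2).mean())
    else:
        per_chrom = pd.DataFrame(columns=["chrom", "n_cases", "fraction"])
        per_sample = pd.DataFrame(columns=["sample", "n_chromosomes"])
        multi = 0.0
    return CTLPSummary(
        n_samples=n_samples,
        n_positive=n_pos,
        incidence=n_pos / n_samples,
        per_chrom=per_chrom,
        per_sample=per_sample,
        multi_chromosome_fraction=multi,
    )
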