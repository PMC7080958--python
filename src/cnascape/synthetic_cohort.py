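"""Synthetic segmented copy-number cohorts with known ground truth.

The generator emulates the statistical structure of a segmented tumor
cohort at the *segment* level (the pipeline consumes segments, so probe
simulation and re-segmentation are out of scope): per-chromosome baseline
partitions with small Gaussian jitter on segment means, arm-level
gains/losses drawn from per-arm *exclusive* gain-or-loss propensities
(which induces the negative arm gain/loss frequency correlation seen in
real tumor cohorts), focal events with log-uniform sizes, chromosomes
carrying an oscillating two-state chromothripsis-like pattern with an
exact planted switch count, optional breakpoint-enriched bins, and a
planted clinically-labelled subgroup (3q gain without 3p loss, tagged
HPV-positive/nasopharynx by default).

All coordinates are integers and every random draw flows through one
seeded :class:`numpy.random.Generator`, so identical config + seed gives
byte-identical SEG output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breakpoint_hotspots import extract_breakpoints
from .genome_model import GenomeBuild, make_bins, toy_build
from .seg_io import ClinicalTable, Cohort

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_arm_propensities",
    "simulate_cohort",
    "simulate_chromothripsis",
    "plant_hotspot",
]


def default_arm_propensities(build: GenomeBuild) -> dict[str, tuple[str, float]]:
    """Per-arm exclusive gain-or-loss propensities.

    Arms are gain-prone or loss-prone, never both, mirroring the
    observation that frequently altered chromosome arms tend to be either
    gained or lost.  For hg19 the prone arms follow the classic squamous
    pattern (3q/5p/8q/20q gains, 3p/5q/8p/13q/18q/21q losses); the toy
    build uses an analogous six-arm pattern.
    """
    if build.name == "toy":
        return {
            "1p": ("loss", 0.25),
            "1q": ("gain", 0.30),
            "2p": ("gain", 0.20),
            "2q": ("loss", 0.30),
            "3p": ("loss", 0.40),
            "3q": ("gain", 0.40),
        }
    table = {
        "3q": ("gain", 0.40), "5p": ("gain", 0.35), "8q": ("gain", 0.40),
        "20q": ("gain", 0.25),
        "3p": ("loss", 0.40), "5q": ("loss", 0.30), "8p": ("loss", 0.35),
        "13q": ("loss", 0.30), "18q": ("loss", 0.30), "21q": ("loss", 0.25),
    }
    return {arm: v for arm, v in table.items() if arm in build.arm_labels}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a segmented cohort with realistic event amplitudes
    relative to the +-0.2 calling thresholds: segment-mean jitter sd 0.05,
    arm events of amplitude 0.5 covering 60-95% of an arm, focal events of
    amplitude 0.6 and log-uniform 0.2-5 Mb sizes, and chromothripsis-like
    chromosomes with 24 status switches of amplitude 0.6 on 0.5-3 Mb
    segments in 5% of samples.
    """

    build: GenomeBuild = field(default_factory=toy_build)
    n_samples: int = 100
    seed: int = 0
    # baseline segmentation
    mean_segment_length: float = 5e6
    noise_sd: float = 0.05
    # arm-level events (exclusive per-arm direction)
    arm_propensities: Mapping[str, tuple[str, float]] | None = None
    arm_amplitude: float = 0.5
    arm_fraction_range: tuple[float, float] = (0.6, 0.95)
    # focal events
    focal_rate: float = 2.0
    focal_size_range: tuple[float, float] = (2e5, 5e6)
    focal_amplitude: float = 0.6
    # chromothripsis-like chromosomes
    ctlp_fraction: float = 0.05
    ctlp_n_oscillations: int = 24
    ctlp_amplitude: float = 0.6
    ctlp_segment_size_range: tuple[float, float] = (5e5, 3e6)
    ctlp_chrom: str | None = None  # default: chr8 on hg19, largest otherwise
    # breakpoint-enriched bins: (chrom, bin_start, multiplier)
    hotspots: Sequence[tuple[str, int, float]] = ()
    hotspot_bin_width: int = 1_000_000
    # planted subgroup (HPV-like: 3q gain, no 3p loss)
    subgroup_fraction: float = 0.3
    subgroup_force: Sequence[tuple[str, str]] = (("3q", "gain"),)
    subgroup_ban: Sequence[tuple[str, str]] = (("3p", "loss"),)
    subgroup_suppress_other_arms: bool = False
    subgroup_site: str = "nasopharynx"
    subgroup_hpv: str = "yes"
    background_hpv_rate: float = 0.05
    clinical_unknown_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("ctlp_fraction", "subgroup_fraction",
                     "background_hpv_rate", "clinical_unknown_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.focal_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise sd must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.focal_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid focal_size_range")
        if hi > max(self.build.chrom_lengths.values()):
            raise ValueError("focal size exceeds the largest chromosome")

    def resolved_propensities(self) -> dict[str, tuple[str, float]]:
        if self.arm_propensities is not None:
            return dict(self.arm_propensities)
        return default_arm_propensities(self.build)

    def resolved_ctlp_chrom(self) -> str:
        if self.ctlp_chrom is not None:
            return self.ctlp_chrom
        if "8" in self.build.chrom_lengths and self.build.name == "hg19":
            return "8"
        return max(self.build.chroms, key=self.build.length)


@dataclass(frozen=True)
class GroundTruth:
    """Planted events of one simulated cohort."""

    arm_events: pd.DataFrame  # sample, arm, type
    focal_events: pd.DataFrame  # sample, chrom, start, end, type
    ctlp: pd.DataFrame  # sample, chrom, start, end, n_switches
    subgroup: pd.Series  # sample -> bool
    hotspots: tuple  # (chrom, bin_start, multiplier) as planted


def simulate_chromothripsis(
    chrom_len: int,
    n_oscillations: int,
    amplitude: float,
    size_range: tuple[float, float],
    rng: np.random.Generator | int | None = None,
    start: int | None = None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """One chromosome with an oscillating two-state pattern.

    Returns segments covering ``[0, chrom_len)`` whose retained-segment
    status-switch count is exactly ``n_oscillations`` by construction:
    the interior alternates between baseline and baseline+amplitude.  An
    odd switch count ends the pattern at the chromosome end (parity of a
    closed oscillation is even).  ``start`` places the oscillating block;
    default is a uniform random feasible position.
    """
    if n_oscillations < 1:
        raise ValueError("n_oscillations must be >= 1")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = int(size_range[0]), int(size_range[1])
    m = n_oscillations if n_oscillations % 2 == 0 else n_oscillations
    # even count: m interior segments (a,0,...,a,0) closed by flanks;
    # odd count: m interior segments (a,0,...,a) running to the chromosome end
    if m * lo > chrom_len:
        raise ValueError(
            f"chromosome of {chrom_len} bp too small for {n_oscillations} "
            f"oscillations at minimum segment size {lo}"
        )
    sizes = rng.integers(lo, hi + 1, size=m)
    while sizes.sum() > chrom_len:
        sizes = rng.integers(lo, hi + 1, size=m)
    block = int(sizes.sum())
    if n_oscillations % 2 == 0:
        if start is None:
            start = int(rng.integers(0, chrom_len - block + 1))
    else:
        start = chrom_len - block  # pattern runs to the chromosome end
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    shifts = np.where(np.arange(m) % 2 == 0, amplitude, 0.0)
    rows = []
    if start > 0:
        rows.append((0, int(start), 0.0))
    for i in range(m):
        rows.append((int(bounds[i]), int(bounds[i + 1]), float(shifts[i])))
    if bounds[-1] < chrom_len:
        rows.append((int(bounds[-1]), chrom_len, 0.0))
    df = pd.DataFrame(rows, columns=["start", "end", "log2"])
    if noise_sd > 0:
        df["log2"] += rng.normal(0.0, noise_sd, size=len(df))
    return df


def _draw_arm_events(
    rng: np.random.Generator,
    config: SimulationConfig,
    in_subgroup: bool,
) -> list[tuple[str, str]]:
    """Planted (arm, type) pairs for one sample."""
    props = config.resolved_propensities()
    forced = set(map(tuple, config.subgroup_force)) if in_subgroup else set()
    banned = set(map(tuple, config.subgroup_ban)) if in_subgroup else set()
    events: list[tuple[str, str]] = []
    for arm, (etype, prob) in props.items():
        if (arm, etype) in forced or (arm, etype) in banned:
            continue  # handled explicitly below / suppressed
        if in_subgroup and config.subgroup_suppress_other_arms:
            continue
        if rng.random() < prob:
            events.append((arm, etype))
    events.extend(sorted(forced))
    return events


def _sample_segments(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    in_subgroup: bool,
    with_ctlp: bool,
    truth: dict[str, list],
) -> pd.DataFrame:
    build = config.build
    arm_events = _draw_arm_events(rng, config, in_subgroup)
    for arm, etype in arm_events:
        truth["arm"].append((sample_id, arm, etype))

    # focal events across the genome, chromosomes weighted by length
    n_focal = rng.poisson(config.focal_rate)
    chrom_list = build.chroms
    weights = np.array([build.length(c) for c in chrom_list], dtype=float)
    weights /= weights.sum()
    focal: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_list}
    lo, hi = config.focal_size_range
    for _ in range(n_focal):
        chrom = str(rng.choice(chrom_list, p=weights))
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        size = min(size, build.length(chrom) - 1)
        s = int(rng.integers(0, build.length(chrom) - size))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        focal[chrom].append((s, s + size, sign * config.focal_amplitude))
        truth["focal"].append(
            (sample_id, chrom, s, s + size, "gain" if sign > 0 else "loss")
        )

    ctlp_chrom = config.resolved_ctlp_chrom() if with_ctlp else None

    frames = []
    for chrom in chrom_list:
        length = build.length(chrom)
        if chrom == ctlp_chrom:
            seg = simulate_chromothripsis(
                length,
                config.ctlp_n_oscillations,
                config.ctlp_amplitude,
                config.ctlp_segment_size_range,
                rng=rng,
                noise_sd=0.0,
            )
            osc = seg[seg["log2"] != 0.0]
            truth["ctlp"].append(
                (sample_id, chrom, int(osc["start"].min()), int(osc["end"].max()),
                 config.ctlp_n_oscillations)
            )
            seg = seg.copy()
            seg["log2"] += rng.normal(0.0, config.noise_sd, size=len(seg))
            seg.insert(0, "chrom", chrom)
            frames.append(seg)
            continue

        # shifted intervals on this chromosome
        shifts: list[tuple[int, int, float]] = list(focal[chrom])
        for arm, etype in arm_events:
            if arm[:-1] != chrom:
                continue
            _, a_s, a_e = build.arm_interval(arm)
            frac = rng.uniform(*config.arm_fraction_range)
            span = int(frac * (a_e - a_s))
            if rng.random() < 0.5:
                iv = (a_s, a_s + span)
            else:
                iv = (a_e - span, a_e)
            amp = config.arm_amplitude if etype == "gain" else -config.arm_amplitude
            shifts.append((iv[0], iv[1], amp))

        n_cuts = rng.poisson(length / config.mean_segment_length)
        cuts = rng.integers(1, length, size=n_cuts) if n_cuts else np.empty(0, int)
        bounds = {0, length}
        bounds.update(int(c) for c in cuts)
        for s, e, _ in shifts:
            bounds.update((int(s), int(e)))
        bounds = np.array(sorted(bounds), dtype=np.int64)
        starts, ends = bounds[:-1], bounds[1:]
        mids = (starts + ends) // 2
        log2 = rng.normal(0.0, config.noise_sd, size=len(starts))
        for s, e, amp in shifts:
            log2 = log2 + np.where((mids >= s) & (mids < e), amp, 0.0)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "log2": log2})
        )

    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "sample", sample_id)
    return df


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[Cohort, GroundTruth, ClinicalTable]:
    """Generate a cohort, its planted ground truth and a clinical table.

    Deterministic for a given config and seed (``seed`` overrides
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    subgroup = rng.random(n) < config.subgroup_fraction
    with_ctlp = rng.random(n) < config.ctlp_fraction

    truth: dict[str, list] = {"arm": [], "focal": [], "ctlp": []}
    frames = []
    clin_rows = []
    site_names = ["oral cavity", "oropharynx", "hypopharynx", "larynx", "sinonasal"]
    site_probs = np.array([0.61, 0.10, 0.06, 0.15, 0.08])
    for i, sid in enumerate(sample_ids):
        frames.append(
            _sample_segments(rng, config, sid, bool(subgroup[i]), bool(with_ctlp[i]), truth)
        )
        if subgroup[i]:
            site, hpv = config.subgroup_site, config.subgroup_hpv
        else:
            site = str(rng.choice(site_names, p=site_probs / site_probs.sum()))
            if rng.random() < config.clinical_unknown_rate:
                hpv = "unknown"
            else:
                hpv = "yes" if rng.random() < config.background_hpv_rate else "no"
        tobacco = "yes" if rng.random() < 0.69 else "no"
        alcohol = "yes" if rng.random() < 0.56 else "no"
        clin_rows.append((sid, site, hpv, tobacco, alcohol))

    cohort = Cohort.from_frame(pd.concat(frames, ignore_index=True), config.build)
    clinical = ClinicalTable(
        df=pd.DataFrame(
            clin_rows, columns=["sample_id", "site", "hpv", "tobacco", "alcohol"]
        )
    )
    gt = GroundTruth(
        arm_events=pd.DataFrame(truth["arm"], columns=["sample", "arm", "type"]),
        focal_events=pd.DataFrame(
            truth["focal"], columns=["sample", "chrom", "start", "end", "type"]
        ),
        ctlp=pd.DataFrame(
            truth["ctlp"], columns=["sample", "chrom", "start", "end", "n_switches"]
        ),
        subgroup=pd.Series(subgroup, index=sample_ids, name="subgroup"),
        hotspots=tuple(config.hotspots),
    )
    if config.hotspots:
        for chrom, bin_start, mult in config.hotspots:
            cohort = plant_hotspot(
                cohort, chrom, int(bin_start),
                int(bin_start) + config.hotspot_bin_width, float(mult), rng=rng,
            )
    return cohort, gt, clinical


def plant_hotspot(
    cohort: Cohort,
    chrom: str,
    bin_start: int,
    bin_end: int,
    multiplier: float,
    rng: np.random.Generator | int | None = None,
    spike_len: int = 20_000,
    spike_amplitude: float = 0.6,
    min_margin: int = 10_000,
) -> Cohort:
    """Inject extra breakpoint-generating spikes into one bin.

    Short high-amplitude spike segments are inserted so that the bin's
    expected breakpoint count is ``multiplier`` times the cohort's
    genome-wide per-bin background (each spike contributes two boundaries
    with |delta| above the breakpoint threshold).  ``multiplier == 1``
    returns the cohort unchanged.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if chrom not in cohort.build.chrom_lengths:
        raise ValueError(f"bin chromosome {chrom!r} not in build")
    if multiplier == 1:
        return cohort
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    grid = make_bins(cohort.build, max(bin_end - bin_start, 1))
    background = len(extract_breakpoints(cohort)) / grid.n_bins
    n_spikes = max(1, int(round((multiplier - 1) * background / 2)))
    df = cohort.df.copy()
    samples = cohort.samples
    new_rows = []
    placed = 0
    attempts = 0
    while placed < n_spikes and attempts < n_spikes * 100:
        attempts += 1
        sid = samples[int(rng.integers(0, len(samples)))]
        pos = int(rng.integers(bin_start, bin_end - spike_len))
        sel = (
            (df["sample"] == sid)
            & (df["chrom"] == chrom)
            & (df["start"] <= pos - min_margin)
            & (df["end"] >= pos + spike_len + min_margin)
        )
        idx = df.index[sel]
        if not len(idx):
            continue
        i = idx[0]
        row = df.loc[i]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        left = row.copy()
        left["end"] = pos
        mid = row.copy()
        mid["start"], mid["end"] = pos, pos + spike_len
        mid["log2"] = row["log2"] + sign * spike_amplitude
        right = row.copy()
        right["start"] = pos + spike_len
        df = df.drop(index=i)
        new_rows.append(pd.DataFrame([left, mid, right]))
        placed += 1
    if new_rows:
        df = pd.concat([df] + new_rows, ignore_index=True)
    return Cohort.from_frame(df, cohort.build)
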