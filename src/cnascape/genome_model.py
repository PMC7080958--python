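"""Reference-genome coordinate frame.

Everything downstream (state frequencies, breakpoint binning, permutation
nulls, arm-level event calls) is expressed against one :class:`GenomeBuild`:
an ordered set of chromosomes with lengths, p/q arm boundaries derived from
centromere positions, telomere exclusion margins, and a fixed-width bin grid.

Internal coordinates are 0-based half-open throughout; readers for 1-based
inclusive dialects convert on input.  Sex chromosomes are excluded from the
default analysis set to avoid gender bias in cohort frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "BinGrid",
    "RegionSet",
    "normalize_chrom",
    "load_cytoband",
    "load_chrom_sizes",
    "make_bins",
    "exclusion_zones",
    "toy_build",
    "hg19_build",
]

#: default width in bp treated as telomeric at each chromosome end
#: (UCSC gap-track convention)
DEFAULT_TELOMERE_SIZE = 10_000

_SEX_CHROMS = frozenset({"x", "y"})


def normalize_chrom(name: object) -> str:
    """Normalize a chromosome name: strip a leading ``chr``, lower-case.

    ``"chr1"``, ``"Chr1"`` and ``"1"`` all map to ``"1"``; ``"chrX"`` to
    ``"x"``.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.lower()


def is_sex_chrom(name: object) -> bool:
    return normalize_chrom(name) in _SEX_CHROMS


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome sizes, arm boundaries and exclusion margins.

    Parameters
    ----------
    name :
        Build label, e.g. ``"hg19"`` or ``"toy"``.
    chrom_lengths :
        Ordered mapping of normalized chromosome name to length in bp.
    centromeres :
        Per chromosome, the centromere interval (0-based half-open).
        Chromosomes absent from this mapping are *arm-less*: they are kept
        for binning and breakpoint analysis but skipped by arm-level calls.
    telomere_size :
        Width in bp treated as telomeric at each chromosome end.
    """

    name: str
    chrom_lengths: Mapping[str, int]
    centromeres: Mapping[str, tuple[int, int]]
    telomere_size: int = DEFAULT_TELOMERE_SIZE

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if not (isinstance(length, (int, np.integer)) and length > 0):
                raise ValueError(
                    f"chromosome {chrom!r} length must be a positive integer, "
                    f"got {length!r}"
                )
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"centromere given for unknown chromosome {chrom!r}")
            length = self.chrom_lengths[chrom]
            if not (0 <= cs <= ce <= length):
                raise ValueError(
                    f"centromere {cs}-{ce} outside chromosome {chrom!r} [0,{length})"
                )
        if self.telomere_size < 0:
            raise ValueError("telomere_size must be >= 0")

    # -- basic accessors ---------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def length(self, chrom: str) -> int:
        return int(self.chrom_lengths[chrom])

    def has_arms(self, chrom: str) -> bool:
        return chrom in self.centromeres

    def arms(self, chrom: str) -> dict[str, tuple[int, int]]:
        """p/q arm intervals of one chromosome (empty dict if arm-less)."""
        if chrom not in self.centromeres:
            return {}
        cs, ce = self.centromeres[chrom]
        out: dict[str, tuple[int, int]] = {}
        if cs > 0:
            out["p"] = (0, int(cs))
        if ce < self.length(chrom):
            out["q"] = (int(ce), self.length(chrom))
        return out

    def arm_intervals(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield ``(arm_label, chrom, start, end)`` over all arms, e.g. ``("3q", "3", ...)``."""
        for chrom in self.chroms:
            for arm, (s, e) in self.arms(chrom).items():
                yield f"{chrom}{arm}", chrom, s, e

    @property
    def arm_labels(self) -> list[str]:
        return [label for label, *_ in self.arm_intervals()]

    def arm_interval(self, label: str) -> tuple[str, int, int]:
        """Resolve an arm label like ``"3q"`` to ``(chrom, start, end)``."""
        chrom, arm = label[:-1], label[-1]
        arms = self.arms(chrom)
        if arm not in arms:
            raise KeyError(f"no arm {label!r} in build {self.name!r}")
        s, e = arms[arm]
        return chrom, s, e


@dataclass(frozen=True)
class RegionSet:
    """A labelled list of genomic intervals (0-based half-open).

    ``df`` has columns ``chrom``, ``start``, ``end``; sorted by chromosome
    appearance order then start.
    """

    label: str
    df: pd.DataFrame

    @classmethod
    def from_intervals(
        cls,
        label: str,
        intervals: Iterable[tuple[str, int, int]],
        build: GenomeBuild | None = None,
    ) -> "RegionSet":
        rows = [(normalize_chrom(c), int(s), int(e)) for c, s, e in intervals]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls._finalize(label, df, build)

    @classmethod
    def from_bed(
        cls, path, label: str | None = None, build: GenomeBuild | None = None
    ) -> "RegionSet":
        """Read a 3+ column BED file (0-based half-open)."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
        )
        df["chrom"] = df["chrom"].map(normalize_chrom)
        return cls._finalize(label or str(path), df, build)

    @classmethod
    def _finalize(
        cls, label: str, df: pd.DataFrame, build: GenomeBuild | None
    ) -> "RegionSet":
        df = df.copy()
        if (df["start"] < 0).any():
            raise ValueError(f"{label}: negative interval start")
        if build is not None:
            keep = df["chrom"].isin(build.chrom_lengths)
            df = df[keep].copy()
            lengths = df["chrom"].map(build.chrom_lengths)
            df["start"] = df["start"].clip(lower=0)
            df["end"] = np.minimum(df["end"], lengths)
            df = df[df["start"] < df["end"]]
            order = {c: i for i, c in enumerate(build.chroms)}
            df = df.sort_values(
                ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
            )
        else:
            df = df.sort_values(["chrom", "start"])
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"{label}: empty or inverted interval")
        return cls(label, df.reset_index(drop=True))

    def to_bed(self, path) -> None:
        out = self.df.copy()
        out["name"] = self.label
        out["chrom"] = "chr" + out["chrom"].astype(str)
        out.to_csv(path, sep="\t", header=False, index=False)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of intervals on one chromosome."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.df)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside an interval of this set."""
        positions = np.asarray(positions, dtype=np.int64)
        mask = np.zeros(positions.shape, dtype=bool)
        for s, e in self.intervals(chrom):
            mask |= (positions >= s) & (positions < e)
        return mask


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling every chromosome of a build.

    The final bin of each chromosome is truncated at the chromosome end and
    retained.  Genome-wide bin indices are contiguous in chromosome order.
    """

    build: GenomeBuild
    width: int
    df: pd.DataFrame = field(repr=False)  # chrom, start, end; index = bin id
    offsets: Mapping[str, int] = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(dtype=np.int64)

    def n_bins_chrom(self, chrom: str) -> int:
        return int(-(-self.build.length(chrom) // self.width))

    def locate(self, chrom: str, positions) -> np.ndarray:
        """Map positions on a chromosome to genome-wide bin indices."""
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and (
            positions.min() < 0 or positions.max() >= self.build.length(chrom)
        ):
            raise ValueError(f"position outside chromosome {chrom!r}")
        return self.offsets[chrom] + positions // self.width

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_bins_chrom(chrom))


def make_bins(build: GenomeBuild, width: int = 1_000_000) -> BinGrid:
    """Tile every chromosome with ``width``-bp bins (last bin truncated)."""
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    width = int(width)
    rows = []
    offsets: dict[str, int] = {}
    idx = 0
    for chrom in build.chroms:
        offsets[chrom] = idx
        length = build.length(chrom)
        for start in range(0, length, width):
            rows.append((chrom, start, min(start + width, length)))
            idx += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return BinGrid(build=build, width=width, df=df, offsets=offsets)


def exclusion_zones(build: GenomeBuild) -> RegionSet:
    """Telomeric margins and centromeres, per chromosome.

    Pure function of the build: positions inside these intervals are ignored
    by breakpoint extraction and excluded from permutation placement.
    """
    t = build.telomere_size
    intervals: list[tuple[str, int, int]] = []
    for chrom in build.chroms:
        length = build.length(chrom)
        if t > 0:
            intervals.append((chrom, 0, min(t, length)))
        if chrom in build.centromeres:
            cs, ce = build.centromeres[chrom]
            if cs < ce:
                intervals.append((chrom, cs, ce))
        if t > 0 and length - t > 0:
            intervals.append((chrom, max(length - t, 0), length))
    return RegionSet.from_intervals("exclusion", intervals, build=build)


# -- construction from files ----------------------------------------------


def load_cytoband(
    path,
    name: str = "custom",
    telomere_size: int = DEFAULT_TELOMERE_SIZE,
    keep_sex: bool = False,
) -> GenomeBuild:
    """Build a :class:`GenomeBuild` from a UCSC-dialect cytoband file.

    Expects 5 tab-delimited columns (chrom, start, end, band, gieStain).
    Chromosome length is the maximum band end; the centromere is the union
    of ``acen``-stained bands.  Chromosomes without any acen band are kept
    but flagged arm-less with a warning.  X/Y are dropped unless
    ``keep_sex``.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "band", "stain"],
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if not keep_sex:
        df = df[~df["chrom"].isin(_SEX_CHROMS)]
    if df.empty:
        raise ValueError(f"{path}: no usable cytoband rows")

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    lengths: dict[str, int] = {}
    centromeres: dict[str, tuple[int, int]] = {}
    armless: list[str] = []
    for chrom in sorted(df["chrom"].unique(), key=chrom_key):
        sub = df[df["chrom"] == chrom]
        lengths[chrom] = int(sub["end"].max())
        acen = sub[sub["stain"] == "acen"]
        if acen.empty:
            armless.append(chrom)
        else:
            centromeres[chrom] = (int(acen["start"].min()), int(acen["end"].max()))
    if armless:
        warnings.warn(
            f"no acen band for chromosome(s) {', '.join(armless)}: "
            "flagged arm-less and excluded from arm-level calls",
            stacklevel=2,
        )
    return GenomeBuild(
        name=name,
        chrom_lengths=lengths,
        centromeres=centromeres,
        telomere_size=telomere_size,
    )


def load_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column chromosome-sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {normalize_chrom(c): int(l) for c, l in zip(df["chrom"], df["length"])}


# -- built-in builds -------------------------------------------------------


def toy_build(telomere_size: int = DEFAULT_TELOMERE_SIZE) -> GenomeBuild:
    """Small 3-chromosome build (120/100/80 Mb) for fast tests and examples."""
    return GenomeBuild(
        name="toy",
        chrom_lengths={"1": 120_000_000, "2": 100_000_000, "3": 80_000_000},
        centromeres={
            "1": (55_000_000, 65_000_000),
            "2": (45_000_000, 50_000_000),
            "3": (35_000_000, 40_000_000),
        },
        telomere_size=telomere_size,
    )


def hg19_build(telomere_size: int = DEFAULT_TELOMERE_SIZE) -> GenomeBuild:
    """hg19/GRCh37 autosomes from the packaged condensed cytoband file."""
    ref = resources.files("cnascape.data") / "hg19_cytoband_condensed.tsv"
    with resources.as_file(ref) as p:
        return load_cytoband(p, name="hg19", telomere_size=telomere_size)


def packaged_region_set(which: str, build: GenomeBuild | None = None) -> RegionSet:
    """Load a packaged demo region set: ``"cfs"`` or ``"nfr"``.

    These are small synthetic/illustrative interval lists shipped for
    examples and tests; they are not curated fragile-site catalogs.
    """
    fname = {"cfs": "cfs_demo_synthetic.bed", "nfr": "nfr_demo_synthetic.bed"}[which]
    ref = resources.files("cnascape.data") / fname
    with resources.as_file(ref) as p:
        return RegionSet.from_bed(p, label=which.upper(), build=build)
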