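"""Read/write segmented copy-number tables, region files and clinical data.

SEG files on disk are tab-delimited and 1-based inclusive (the common
dialect of segmentation output); they are converted to 0-based half-open
coordinates on read.  Both the TCGA header
(``ID/chrom/loc.start/loc.end/num.mark/seg.mean``) and a minimal 5-column
form are accepted, auto-detected by header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_model import GenomeBuild, is_sex_chrom, normalize_chrom

__all__ = [
    "Cohort",
    "ClinicalTable",
    "read_seg",
    "write_seg",
    "read_table",
    "write_table",
    "read_clinical",
    "write_run_summary",
]

logger = logging.getLogger(__name__)

#: aliases for SEG column names, lower-cased
_SEG_ALIASES = {
    "sample": "sample",
    "sample_id": "sample",
    "sampleid": "sample",
    "id": "sample",
    "chrom": "chrom",
    "chromosome": "chrom",
    "chr": "chrom",
    "start": "start",
    "loc.start": "start",
    "loc_start": "start",
    "end": "end",
    "loc.end": "end",
    "loc_end": "end",
    "num.mark": "n_probes",
    "num_mark": "n_probes",
    "num_probes": "n_probes",
    "n_probes": "n_probes",
    "seg.mean": "log2",
    "seg_mean": "log2",
    "segment_mean": "log2",
    "log2": "log2",
    "log2ratio": "log2",
    "mean": "log2",
}

SITES = (
    "oral cavity",
    "nasopharynx",
    "oropharynx",
    "hypopharynx",
    "larynx",
    "sinonasal",
    "unknown",
)


@dataclass(frozen=True)
class Cohort:
    """Segmented profiles of many samples against one genome build.

    ``df`` columns: ``sample``, ``chrom``, ``start``, ``end``, ``log2``
    (plus optional ``n_probes``); 0-based half-open coordinates, sorted by
    sample, chromosome order, start; per sample+chromosome segments are
    non-overlapping.
    """

    df: pd.DataFrame
    build: GenomeBuild

    @classmethod
    def from_frame(cls, df: pd.DataFrame, build: GenomeBuild) -> "Cohort":
        required = ["sample", "chrom", "start", "end", "log2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing cohort columns: {missing}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        unknown = ~df["chrom"].isin(build.chrom_lengths)
        if unknown.any():
            raise ValueError(
                f"unknown chromosome(s) {sorted(df.loc[unknown, 'chrom'].unique())}"
            )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["log2"] = df["log2"].astype(float)
        if not np.isfinite(df["log2"]).all():
            raise ValueError("non-finite log2 value in cohort frame")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"empty segment {bad['sample']} {bad['chrom']}:"
                f"{bad['start']}-{bad['end']}"
            )
        # clip to chromosome bounds
        lengths = df["chrom"].map(build.chrom_lengths)
        df["start"] = df["start"].clip(lower=0)
        df["end"] = np.minimum(df["end"], lengths)
        order = {c: i for i, c in enumerate(build.chroms)}
        df["_c"] = df["chrom"].map(order)
        df = df.sort_values(["sample", "_c", "start"], kind="mergesort")
        df = df.drop(columns="_c").reset_index(drop=True)
        # overlap check within sample+chromosome
        same = (df["sample"] == df["sample"].shift()) & (
            df["chrom"] == df["chrom"].shift()
        )
        overlap = same & (df["start"] < df["end"].shift())
        if overlap.any():
            bad = df[overlap].iloc[0]
            raise ValueError(
                f"overlapping segments for sample {bad['sample']!r} "
                f"chromosome {bad['chrom']!r}"
            )
        return cls(df=df, build=build)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    @property
    def n_samples(self) -> int:
        return self.df["sample"].nunique()

    def sample_chrom_groups(self):
        """Iterate ``((sample, chrom), frame)`` in sorted order."""
        return self.df.groupby(["sample", "chrom"], sort=False)


def read_seg(path, build: GenomeBuild) -> Cohort:
    """Read a SEG file (1-based inclusive on disk) into a :class:`Cohort`.

    X/Y rows are dropped with a logged count; rows on chromosomes unknown
    to the build are skipped with a warning; rows with missing log2 are
    dropped with a warning.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {}
    for c in raw.columns:
        key = _SEG_ALIASES.get(str(c).strip().lower().replace('"', ""))
        if key and key not in cols.values():
            cols[c] = key
    raw = raw.rename(columns=cols)
    required = ["sample", "chrom", "start", "end", "log2"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: unrecognized SEG header, missing {missing}")

    df = raw[[c for c in ("sample", "chrom", "start", "end", "n_probes", "log2")
              if c in raw.columns]].copy()
    try:
        df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
        df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable coordinate ({exc})") from exc
    df["log2"] = pd.to_numeric(df["log2"], errors="coerce")
    df["chrom"] = df["chrom"].map(normalize_chrom)

    n_sex = int(df["chrom"].map(is_sex_chrom).sum())
    if n_sex:
        logger.info("dropped %d X/Y segment rows", n_sex)
        df = df[~df["chrom"].map(is_sex_chrom)]
    unknown = ~df["chrom"].isin(build.chrom_lengths)
    if unknown.any():
        logger.warning(
            "skipped %d rows on chromosomes unknown to build %s: %s",
            int(unknown.sum()), build.name,
            sorted(df.loc[unknown, "chrom"].unique()),
        )
        df = df[~unknown]
    n_nan = int(df["log2"].isna().sum())
    if n_nan:
        logger.warning("dropped %d segment rows with missing log2", n_nan)
        df = df.dropna(subset=["log2"])
    if df.empty:
        raise ValueError(f"{path}: no usable segment rows")

    df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
    return Cohort.from_frame(df.reset_index(drop=True), build)


def write_seg(cohort: Cohort, path) -> None:
    """Write a cohort back to disk in 1-based inclusive SEG form."""
    out = cohort.df.copy()
    out["start"] = out["start"] + 1
    out = out.rename(columns={"sample": "ID", "chrom": "chrom",
                              "start": "loc.start", "end": "loc.end",
                              "log2": "seg.mean"})
    cols = ["ID", "chrom", "loc.start", "loc.end"]
    if "n_probes" in out.columns:
        cols.append("n_probes")
        out = out.rename(columns={"n_probes": "num.mark"})
        cols[-1] = "num.mark"
    cols.append("seg.mean")
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


#: columns rendered in scientific notation with 6 significant digits
_SCI_COLS = ("p_raw", "p_bonferroni", "p_value")


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a deterministic column order.

    p-value columns are rendered in scientific notation with 6 significant
    digits; other floats with ``%.6g``.  Round-trips through
    :func:`read_table`.
    """
    out = records.copy()
    for col in out.columns:
        if col in _SCI_COLS:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.5e}"
            )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- clinical annotation ---------------------------------------------------

_YESNO = {"yes": "yes", "y": "yes", "true": "yes", "1": "yes",
          "no": "no", "n": "no", "false": "no", "0": "no"}


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotation (site, HPV, tobacco, alcohol, grade).

    Missing values are stored as ``"unknown"``; category labels are
    case-normalized.
    """

    df: pd.DataFrame

    def summarize(self, column: str) -> pd.DataFrame:
        """Category counts and proportions among non-unknown values.

        Returns a frame with columns ``value``, ``count``,
        ``proportion_of_known`` (NaN for the ``unknown`` row).
        """
        counts = self.df[column].value_counts()
        known = int(counts.drop(index="unknown", errors="ignore").sum())
        rows = []
        for value, count in counts.items():
            prop = np.nan if (value == "unknown" or known == 0) else count / known
            rows.append((value, int(count), prop))
        return pd.DataFrame(rows, columns=["value", "count", "proportion_of_known"])

    def proportion(self, column: str, value: str) -> float:
        """Proportion of ``value`` among samples with a known entry."""
        s = self.summarize(column)
        row = s[s["value"] == value]
        return float(row["proportion_of_known"].iloc[0]) if len(row) else 0.0


def read_clinical(path) -> ClinicalTable:
    """Read a tab-delimited clinical table keyed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        if "sample" in df.columns:
            df = df.rename(columns={"sample": "sample_id"})
        else:
            raise ValueError(f"{path}: no sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    for col in df.columns:
        if col == "sample_id":
            continue
        vals = df[col].fillna("").astype(str).str.strip().str.lower()
        vals = vals.replace("", "unknown")
        if col in ("hpv", "tobacco", "alcohol"):
            vals = vals.map(lambda v: _YESNO.get(v, "unknown" if v == "unknown" else v))
            bad = ~vals.isin(("yes", "no", "unknown"))
            if bad.any():
                vals[bad] = "unknown"
        df[col] = vals
    return ClinicalTable(df=df.reset_index(drop=True))


def write_run_summary(path, **fields) -> None:
    """Write a JSON run summary (parameters, seed, per-stage counts)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
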