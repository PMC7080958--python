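"""Cohort clustering on genome-wide copy-number profiles.

Samples are represented as bin vectors — state-encoded (-1/0/+1, robust to
platform signal-scale differences across heterogeneous array datasets) or
length-weighted mean log2 — and clustered agglomeratively with Ward
linkage on Euclidean distances, cut into ``k`` flat clusters (two major
clusters by default).  Cluster composition is summarized against CNA
burden, recurrent arm events and clinical labels (each-cluster-vs-rest
Fisher exact tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .cna_calling import burden_summary, sample_bin_states
from .genome_model import BinGrid, GenomeBuild
from .seg_io import ClinicalTable

__all__ = [
    "build_matrix",
    "ClusterAssignment",
    "ward_cluster",
    "cluster_summary",
    "label_enrichment",
]


def build_matrix(calls: pd.DataFrame, grid: BinGrid, mode: str = "state") -> pd.DataFrame:
    """Bin-by-sample copy-number matrix.

    ``state`` mode applies the per-sample bin-state rule (entries in
    {-1, 0, +1}); ``log2`` mode stores the coverage-weighted mean log2 per
    bin (0 where a sample has no segments).  Rows are genome bins in grid
    order; columns are samples sorted lexicographically.
    """
    samples = sorted(calls["sample"].unique())
    mat = np.zeros((grid.n_bins, len(samples)), dtype=np.float64)
    if mode == "state":
        for j, (sample, sub) in enumerate(
            (s, calls[calls["sample"] == s]) for s in samples
        ):
            mat[:, j] = sample_bin_states(sub, grid)
    elif mode == "log2":
        w = grid.width
        for j, sample in enumerate(samples):
            sub = calls[calls["sample"] == sample]
            weighted = np.zeros(grid.n_bins)
            covered = np.zeros(grid.n_bins)
            for chrom, s, e, log2 in zip(
                sub["chrom"], sub["start"], sub["end"], sub["log2"]
            ):
                off = grid.offsets[chrom]
                first, last = s // w, (e - 1) // w
                if first == last:
                    weighted[off + first] += (e - s) * log2
                    covered[off + first] += e - s
                else:
                    lead = (first + 1) * w - s
                    tail = e - last * w
                    weighted[off + first] += lead * log2
                    covered[off + first] += lead
                    weighted[off + last] += tail * log2
                    covered[off + last] += tail
                    if last > first + 1:
                        weighted[off + first + 1 : off + last] += w * log2
                        covered[off + first + 1 : off + last] += w
            nz = covered > 0
            mat[nz, j] = weighted[nz] / covered[nz]
    else:
        raise ValueError(f"unknown matrix mode {mode!r}")
    return pd.DataFrame(mat, columns=samples)


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat cluster labels plus the underlying linkage tree."""

    labels: pd.Series  # sample -> cluster label in 1..k
    linkage: np.ndarray  # scipy linkage matrix (merge heights)
    k: int

    @property
    def clusters(self) -> list[int]:
        return sorted(self.labels.unique())


def ward_cluster(matrix: pd.DataFrame, k: int = 2) -> ClusterAssignment:
    """Agglomerative Ward clustering of samples on Euclidean distances.

    Columns of ``matrix`` are samples.  The tree is cut into ``k`` flat
    clusters; labels are renumbered 1..k in order of first appearance over
    the (sorted) sample list, so the assignment is deterministic and
    invariant to input column order up to renaming.
    """
    n = matrix.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    X = matrix.to_numpy().T
    order = np.argsort(matrix.columns)
    X = X[order]
    samples = list(np.asarray(matrix.columns)[order])
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return ClusterAssignment(
        labels=pd.Series(labels, index=samples, name="cluster"), linkage=Z, k=k
    )


def cluster_summary(
    assignment: ClusterAssignment,
    calls: pd.DataFrame,
    arm_events: pd.DataFrame,
    build: GenomeBuild,
    top_n: int = 5,
) -> pd.DataFrame:
    """Per-cluster burden and arm-event profile.

    Columns: cluster, n_samples, mean fraction of genome altered, mean arm
    events per sample, and the ``top_n`` most recurrent arm events
    (``arm:type`` joined by commas).
    """
    burden = burden_summary(calls, build).set_index("sample")
    rows = []
    for cl in assignment.clusters:
        members = assignment.labels[assignment.labels == cl].index
        assert len(members) > 0, "empty cluster cannot occur by construction"
        frac = burden.loc[burden.index.intersection(members),
                          "fraction_genome_altered"].mean()
        if len(arm_events):
            sub = arm_events[arm_events["sample"].isin(members)]
            per_sample = len(sub) / len(members)
            top = (
                (sub["arm"] + ":" + sub["type"]).value_counts().head(top_n).index
            )
            top_events = ",".join(top)
        else:
            per_sample, top_events = 0.0, ""
        rows.append(
            {
                "cluster": cl,
                "n_samples": len(members),
                "mean_fraction_altered": float(frac) if not np.isnan(frac) else 0.0,
                "mean_arm_events": per_sample,
                "top_arm_events": top_events,
            }
        )
    return pd.DataFrame(rows)


def label_enrichment(
    assignment: ClusterAssignment,
    clinical: ClinicalTable,
    label: str,
    value: str = "yes",
) -> pd.DataFrame:
    """Each-cluster-vs-rest enrichment of one clinical label value.

    Samples with unknown label are excluded from the denominators.  For
    every cluster a 2x2 table (in-cluster/rest x value/other) is tested
    with a two-sided Fisher exact test.
    """
    clin = clinical.df.set_index("sample_id")[label]
    clin = clin[clin != "unknown"]
    if clin.empty:
        raise ValueError(f"all values of {label!r} are unknown")
    common = assignment.labels.index.intersection(clin.index)
    labels = assignment.labels.loc[common]
    is_value = clin.loc[common] == value
    rows = []
    for cl in assignment.clusters:
        in_cl = labels == cl
        a = int((in_cl & is_value).sum())
        b = int((in_cl & ~is_value).sum())
        c = int((~in_cl & is_value).sum())
        d = int((~in_cl & ~is_value).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "cluster": cl,
                "n": a + b,
                "n_value": a,
                "rest_n": c + d,
                "rest_value": c,
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
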