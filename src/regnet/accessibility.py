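"""Accessibility analysis: normalization, distal-site definition, sample
clustering, fold-change ranking and cut-density profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from regnet.genomic_io import GenomicInterval, TSSAnnotation

__all__ = [
    "TagCountMatrix",
    "RankedPeaks",
    "SpecificSiteSet",
    "normalize_counts",
    "filter_distal",
    "correlation_matrix",
    "hierarchical_cluster",
    "cut_dendrogram",
    "rank_by_fold_change",
    "specific_sites",
    "density_matrix",
    "average_profile",
]


def infer_groups(sample_ids: Iterable[str]) -> dict[str, str]:
    """Default group labeling: everything before the last underscore."""
    out = {}
    for s in sample_ids:
        out[s] = s.rsplit("_", 1)[0] if "_" in s else s
    return out


@dataclass
class TagCountMatrix:
    """Peaks x samples accessibility counts with sample group labels."""

    counts: pd.DataFrame  # index: peak ids, columns: sample ids
    group_of: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative tag counts")
        if not self.group_of:
            self.group_of = infer_groups(self.counts.columns)
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        hits = [s for s in self.counts.columns if self.group_of[s] == group]
        if not hits:
            raise ValueError(f"unknown group label {group!r}")
        return hits

    def group_means(self, group: str) -> pd.Series:
        return self.counts[self.samples_in(group)].mean(axis=1)


@dataclass
class RankedPeaks:
    """Peaks ordered by log2 fold change between two sample groups.

    Ordering is non-increasing in log2FC; ties break lexicographically by
    peak id for determinism.
    """

    peak_ids: list[str]
    log2_fold_change: pd.Series  # indexed by peak id, in ranked order
    group_a: str
    group_b: str
    pseudocount: float


@dataclass
class SpecificSiteSet:
    group: str
    fold: float
    peak_ids: set[str]


def normalize_counts(matrix: TagCountMatrix, scale: float = 1e7) -> TagCountMatrix:
    """Scale each sample column to a common total (default 1e7 tags).

    Guards against double normalization; a zero-total sample is an error.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample {zero.index[0]!r}")
    scaled = matrix.counts * (scale / totals)
    return TagCountMatrix(scaled, dict(matrix.group_of), normalized=True)


def filter_distal(
    peaks: Sequence[GenomicInterval],
    tss: TSSAnnotation,
    min_dist: int = 1500,
) -> list[GenomicInterval]:
    """Retain peaks whose midpoint lies >= min_dist bp from the nearest TSS
    on the same chromosome.  Peaks on TSS-free chromosomes are retained."""
    tss_by_chrom = tss.by_chrom()
    kept = []
    for peak in peaks:
        positions = tss_by_chrom.get(peak.chrom)
        if positions is None or len(positions) == 0:
            kept.append(peak)
            continue
        mid = peak.midpoint
        i = int(np.searchsorted(positions, mid))
        candidates = positions[max(0, i - 1) : i + 1]
        if int(np.abs(candidates - mid).min()) >= min_dist:
            kept.append(peak)
    return kept


def correlation_matrix(
    matrix: TagCountMatrix, log_transform: bool = True
) -> pd.DataFrame:
    """Samples x samples Pearson correlation, on log2(x+1) by default."""
    if matrix.counts.shape[0] < 2:
        raise ValueError("need >= 2 peaks to correlate samples")
    values = matrix.counts
    if log_transform:
        values = np.log2(values + 1.0)
    stds = values.std(axis=0, ddof=0)
    flat = stds[stds == 0]
    if len(flat):
        raise ValueError(f"zero-variance sample {flat.index[0]!r}")
    corr = values.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_cluster(corr: pd.DataFrame):
    """Average-linkage clustering on distance 1 - r.

    Returns ``(linkage_matrix, leaf_order)`` where leaf_order is the list of
    sample ids in dendrogram order.  Input columns are sorted by sample id
    first so the result is deterministic under ties.
    """
    order = sorted(corr.columns)
    corr = corr.loc[order, order]
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [order[i] for i in leaves]


def cut_dendrogram(
    corr: pd.DataFrame, k: int
) -> dict[str, int]:
    """Cut the average-linkage dendrogram into k flat clusters."""
    order = sorted(corr.columns)
    linkage, _ = hierarchical_cluster(corr)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return {s: int(c) for s, c in zip(order, labels)}


def rank_by_fold_change(
    matrix: TagCountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> RankedPeaks:
    """Rank peaks by log2((meanA+pc)/(meanB+pc)), non-increasing; ties break
    lexicographically by peak id."""
    if not matrix.normalized:
        raise ValueError("rank_by_fold_change requires a normalized matrix")
    mean_a = matrix.group_means(group_a)
    mean_b = matrix.group_means(group_b)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    order = sorted(lfc.index, key=lambda p: (-lfc[p], p))
    return RankedPeaks(
        peak_ids=order,
        log2_fold_change=lfc.loc[order],
        group_a=group_a,
        group_b=group_b,
        pseudocount=pseudocount,
    )


def specific_sites(
    ranked: RankedPeaks, fold: float = 4.0
) -> tuple[SpecificSiteSet, SpecificSiteSet]:
    """Split ranked peaks into group-specific sets at an inclusive fold
    threshold: |log2FC| >= log2(fold)."""
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    cut = np.log2(fold)
    lfc = ranked.log2_fold_change
    set_a = set(lfc.index[lfc >= cut])
    set_b = set(lfc.index[lfc <= -cut])
    return (
        SpecificSiteSet(ranked.group_a, fold, set_a),
        SpecificSiteSet(ranked.group_b, fold, set_b),
    )


def density_matrix(
    profiles: Mapping[str, np.ndarray],
    ranked: RankedPeaks,
    window: int = 2000,
    bin: int = 20,
) -> pd.DataFrame:
    """Per-bin cut sums over the window for every ranked peak, rows in
    ranked order.  Row sums equal the total cuts in the window."""
    if window % bin != 0:
        raise ValueError("window must be a multiple of bin")
    rows = []
    for pid in ranked.peak_ids:
        if pid not in profiles:
            raise ValueError(f"missing cut profile for peak {pid!r}")
        cuts = np.asarray(profiles[pid])
        if len(cuts) != window:
            raise ValueError(
                f"profile for {pid!r} has length {len(cuts)}, expected {window}"
            )
        rows.append(cuts.reshape(-1, bin).sum(axis=1))
    cols = [f"bin_{i * bin}" for i in range(window // bin)]
    return pd.DataFrame(rows, index=ranked.peak_ids, columns=cols)


def average_profile(
    profiles: Mapping[str, np.ndarray],
    sites: SpecificSiteSet | Iterable[str],
    window: int = 2000,
) -> np.ndarray:
    """Positionwise mean cut profile over a site set."""
    ids = sorted(sites.peak_ids if isinstance(sites, SpecificSiteSet) else set(sites))
    if not ids:
        raise ValueError("empty site set")
    stack = []
    for pid in ids:
        if pid not in profiles:
            raise ValueError(f"missing cut profile for peak {pid!r}")
        cuts = np.asarray(profiles[pid], dtype=float)
        if len(cuts) != window:
            raise ValueError(f"profile for {pid!r} has wrong length")
        stack.append(cuts)
    return np.mean(stack, axis=0)
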