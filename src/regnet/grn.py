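"""Enhancer-gene assignment and TF network construction.

Peaks are assigned to genes interaction-first (promoter-capture contact
overlapping the peak, highest score wins) with a nearest-TSS fallback.
Network edges require a footprinted motif occurrence of an expressed TF in
a disease-specific peak assigned to an expressed target gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from regnet.accessibility import TagCountMatrix
from regnet.footprinting import Footprint, MotifOccurrence
from regnet.genomic_io import GenomicInterval, Interaction, TSSAnnotation

__all__ = [
    "Assignment",
    "PeakGeneMap",
    "GRN",
    "RecoveryReport",
    "assign_peaks_to_genes",
    "aml_specific_peaks",
    "build_grn",
    "grn_recovery_report",
]


@dataclass(frozen=True)
class Assignment:
    gene_id: str
    evidence: str  # "interaction" or "nearest"
    distance: int  # bp; 0 for interaction evidence


@dataclass
class PeakGeneMap:
    assignments: dict[str, Assignment]
    unmapped: list[str] = field(default_factory=list)

    def __getitem__(self, peak_id: str) -> Assignment:
        return self.assignments[peak_id]

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class GRNNode:
    expression: float
    is_tf: bool


@dataclass
class GRNEdge:
    site_ids: set[str] = field(default_factory=set)

    @property
    def site_count(self) -> int:
        return len(self.site_ids)


@dataclass
class GRN:
    """Directed TF -> target network with site-count edge weights."""

    nodes: dict[str, GRNNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], GRNEdge] = field(default_factory=dict)

    def validate(self) -> None:
        for (src, dst), edge in self.edges.items():
            if src not in self.nodes or dst not in self.nodes:
                raise ValueError(f"edge ({src}, {dst}) references absent node")
            if not self.nodes[src].is_tf:
                raise ValueError(f"edge source {src} is not a TF node")
            if edge.site_count < 1:
                raise ValueError(f"edge ({src}, {dst}) has no supporting sites")

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        self.validate()
        g = nx.DiGraph()
        for name, node in self.nodes.items():
            g.add_node(name, expression=node.expression, is_tf=node.is_tf)
        for (src, dst), edge in self.edges.items():
            g.add_edge(
                src, dst, site_count=edge.site_count, site_ids=sorted(edge.site_ids)
            )
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "GRN":
        grn = cls()
        for name, attrs in g.nodes(data=True):
            grn.nodes[name] = GRNNode(
                float(attrs.get("expression", 0.0)), bool(attrs.get("is_tf", False))
            )
        for src, dst, attrs in g.edges(data=True):
            grn.edges[(src, dst)] = GRNEdge(set(attrs.get("site_ids", ())))
        return grn

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": src,
                "target": dst,
                "site_count": e.site_count,
                "site_ids": ",".join(sorted(e.site_ids)),
            }
            for (src, dst), e in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "site_count", "site_ids"]
        )


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    interactions: Sequence[Interaction],
    tss: TSSAnnotation,
    max_nearest: int = 50_000,
    min_interaction_score: float = 0.0,
) -> PeakGeneMap:
    """Interaction-first peak-to-gene assignment with nearest-TSS fallback.

    A peak overlapping (>= 1 bp) any distal anchor with score >=
    min_interaction_score maps to that interaction's gene (highest score
    wins, ties broken by gene id).  Otherwise the peak maps to the nearest
    TSS within ``max_nearest`` bp of its midpoint, else it is unmapped.
    """
    by_chrom: dict[str, list[Interaction]] = {}
    for x in interactions:
        if x.score >= min_interaction_score:
            by_chrom.setdefault(x.distal_anchor.chrom, []).append(x)
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for rec in tss:
        tss_by_chrom.setdefault(rec.chrom, []).append((rec.position, rec.gene_id))
    for lst in tss_by_chrom.values():
        lst.sort()

    assignments: dict[str, Assignment] = {}
    unmapped: list[str] = []
    for peak in peaks:
        pid = peak.id if peak.id is not None else f"{peak.chrom}:{peak.start}-{peak.end}"
        hits = [
            x
            for x in by_chrom.get(peak.chrom, ())
            if peak.overlaps(x.distal_anchor)
        ]
        if hits:
            best = min(hits, key=lambda x: (-x.score, x.gene_id))
            assignments[pid] = Assignment(best.gene_id, "interaction", 0)
            continue
        cands = tss_by_chrom.get(peak.chrom, [])
        if cands:
            positions = np.array([p for p, _ in cands])
            mid = peak.midpoint
            i = int(np.searchsorted(positions, mid))
            best_d, best_gene = None, None
            for j in range(max(0, i - 1), min(len(cands), i + 1)):
                d = abs(cands[j][0] - mid)
                if best_d is None or (d, cands[j][1]) < (best_d, best_gene):
                    best_d, best_gene = d, cands[j][1]
            if best_d is not None and best_d <= max_nearest:
                assignments[pid] = Assignment(best_gene, "nearest", int(best_d))
                continue
        unmapped.append(pid)
    return PeakGeneMap(assignments, unmapped)


def aml_specific_peaks(
    matrix: TagCountMatrix,
    aml_group: str,
    reference_group: str = "PBSC",
    fold: float = 2.0,
) -> set[str]:
    """Peaks with (mean_aml + 1)/(mean_ref + 1) >= fold on normalized counts."""
    if not matrix.normalized:
        raise ValueError("aml_specific_peaks requires a normalized matrix")
    mean_aml = matrix.group_means(aml_group)
    mean_ref = matrix.group_means(reference_group)
    ratio = (mean_aml + 1.0) / (mean_ref + 1.0)
    return set(ratio.index[ratio >= fold])


def build_grn(
    specific_peaks: set[str],
    footprints: Sequence[Footprint],
    occurrences: Sequence[MotifOccurrence],
    peak_gene_map: PeakGeneMap,
    tf_motifs: Mapping[str, str | Iterable[str]],
    expression: pd.DataFrame,
    samples: Sequence[str],
    motif_lengths: Mapping[str, int],
    window_offset: Mapping[str, int] | int = 0,
    min_fpkm: float = 1.0,
) -> GRN:
    """Build the TF -> target network from footprinted motif occurrences.

    A candidate site is a motif occurrence that overlaps a detected
    footprint (>= 1 bp) inside a disease-specific peak.  For TF t with that
    motif (mean FPKM over ``samples`` >= min_fpkm) in a peak assigned to
    gene g (also expressed), the edge t -> g gains the peak as a supporting
    site.  ``window_offset`` converts peak-relative motif offsets to the
    window-relative footprint coordinates.
    """
    motif_to_tfs: dict[str, list[str]] = {}
    for tf, motifs in tf_motifs.items():
        if tf not in expression.index:
            raise ValueError(f"TF {tf!r} absent from the expression table")
        if isinstance(motifs, str):
            motifs = [motifs]
        for m in motifs:
            motif_to_tfs.setdefault(m, []).append(tf)

    mean_expr = expression[list(samples)].mean(axis=1)

    def offset_of(peak_id: str) -> int:
        return window_offset if isinstance(window_offset, int) else window_offset[peak_id]

    fp_by_peak: dict[str, list[Footprint]] = {}
    for fp in footprints:
        if fp.peak_id in specific_peaks:
            fp_by_peak.setdefault(fp.peak_id, []).append(fp)

    grn = GRN()

    def ensure_node(gene: str, is_tf: bool) -> None:
        if gene not in grn.nodes:
            grn.nodes[gene] = GRNNode(float(mean_expr.get(gene, 0.0)), is_tf)
        elif is_tf:
            grn.nodes[gene].is_tf = True

    for occ in occurrences:
        if occ.peak_id not in specific_peaks or occ.peak_id not in peak_gene_map:
            continue
        tfs = motif_to_tfs.get(occ.motif_id)
        if not tfs:
            continue
        fps = fp_by_peak.get(occ.peak_id)
        if not fps:
            continue
        w_start = occ.offset + offset_of(occ.peak_id)
        w_end = w_start + motif_lengths[occ.motif_id]
        if not any(fp.start < w_end and w_start < fp.end for fp in fps):
            continue
        target = peak_gene_map[occ.peak_id].gene_id
        if target not in expression.index or mean_expr[target] < min_fpkm:
            continue
        for tf in tfs:
            if mean_expr[tf] < min_fpkm:
                continue
            ensure_node(tf, True)
            ensure_node(target, target in tf_motifs)
            grn.edges.setdefault((tf, target), GRNEdge()).site_ids.add(occ.peak_id)
    grn.validate()
    return grn


@dataclass
class RecoveryReport:
    precision: float | None  # None when there are no predictions
    recall: float
    f1: float
    n_predicted: int
    n_true: int
    n_correct: int

    def __str__(self) -> str:
        p = "NA" if self.precision is None else f"{self.precision:.4f}"
        return (
            f"edges predicted={self.n_predicted} true={self.n_true} "
            f"correct={self.n_correct} precision={p} "
            f"recall={self.recall:.4f} F1={self.f1:.4f}"
        )


def grn_recovery_report(
    grn: GRN, true_edges: set[tuple[str, str]]
) -> RecoveryReport:
    """Precision/recall/F1 of directed edges against the planted program."""
    predicted = grn.edge_set()
    correct = predicted & true_edges
    if predicted:
        precision: float | None = len(correct) / len(predicted)
        p_for_f1 = precision
    else:
        precision, p_for_f1 = None, 1.0  # no predictions: precision undefined
    recall = len(correct) / len(true_edges) if true_edges else 1.0
    f1 = (
        2 * p_for_f1 * recall / (p_for_f1 + recall)
        if (p_for_f1 + recall) > 0
        else 0.0
    )
    return RecoveryReport(
        precision, recall, f1, len(predicted), len(true_edges), len(correct)
    )
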