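"""Readers and writers for the external formats the pipeline touches.

All in-memory coordinates are 0-based half-open (BED-native).  Any 1-based
external dialect is converted at the boundary and never leaks inward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TSSAnnotation",
    "TSSRecord",
    "Interaction",
    "PWM",
    "read_bed",
    "write_bed",
    "read_tss",
    "write_tss",
    "read_interactions",
    "write_interactions",
    "read_count_matrix",
    "write_count_matrix",
    "read_pwms",
    "write_pwms",
    "read_fasta",
    "write_fasta",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """Raised when an input file violates its dialect contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    position: int  # 0-based bp
    strand: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")


class TSSAnnotation:
    """Transcription start sites; one or more per gene allowed."""

    def __init__(self, records: Iterable[TSSRecord]):
        self.records: list[TSSRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted TSS positions per chromosome."""
        out: dict[str, list[int]] = {}
        for r in self.records:
            out.setdefault(r.chrom, []).append(r.position)
        return {c: np.asarray(sorted(p)) for c, p in out.items()}

    def positions_of(self, gene_id: str) -> list[TSSRecord]:
        return [r for r in self.records if r.gene_id == gene_id]


@dataclass(frozen=True)
class Interaction:
    """A promoter-capture contact linking a distal anchor to a gene."""

    promoter_anchor: GenomicInterval
    distal_anchor: GenomicInterval
    gene_id: str
    score: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("interaction without gene_id")
        if self.score < 0:
            raise ValueError(f"negative interaction score for {self.gene_id}")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError(
                f"{self.motif_id}: matrix must be 4 x L with L >= 4, got {m.shape}"
            )
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: columns must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p/background) per cell; guaranteed finite (pseudocounted)."""
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        # complement = reverse row order (A<->T, C<->G), reverse columns
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError(f"{motif_id}: negative count")
        reg = counts + pseudocount
        probs = reg / reg.sum(axis=0, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(motif_id, probs, background)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>= 3 whitespace-delimited columns) into intervals.

    Column 4 becomes the interval id, column 6 the strand.  Input order is
    preserved.  An empty file yields an empty list.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if not (0 <= start < end):
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            id_ = fields[3] if len(fields) >= 4 else None
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(GenomicInterval(chrom, start, end, id_, strand))
    ids = [iv.id for iv in intervals if iv.id is not None]
    if len(ids) != len(set(ids)):
        raise FormatError(f"{path}: duplicate interval ids")
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.strand != ".":
                cols.append(iv.id if iv.id is not None else ".")
            if iv.strand != ".":
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# TSS (BED-like: chrom, pos, pos+1, gene_id, score, strand)


def read_tss(path: str | Path) -> TSSAnnotation:
    records = []
    for iv in read_bed_allow_duplicate_ids(path):
        if iv.id is None:
            raise FormatError(f"{path}: TSS record without gene_id (column 4)")
        records.append(TSSRecord(iv.id, iv.chrom, iv.start, iv.strand))
    return TSSAnnotation(records)


def read_bed_allow_duplicate_ids(path: str | Path) -> list[GenomicInterval]:
    """BED reader variant for files where the name column is a gene id that
    may legitimately repeat (multiple TSS per gene)."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid interval")
            id_ = fields[3] if len(fields) >= 4 else None
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(GenomicInterval(fields[0], start, end, id_, strand))
    return intervals


def write_tss(tss: TSSAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in tss:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene_id}\t0\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# BEDPE + gene_id + score (interactions)


def read_interactions(path: str | Path) -> list[Interaction]:
    """BEDPE with columns 1-6 the two anchors (promoter first), column 7 the
    gene id and column 8 a non-negative score."""
    out: list[Interaction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: fewer than 8 columns")
            try:
                prom = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                dist = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                score = float(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                out.append(Interaction(prom, dist, fields[6], score))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for x in interactions:
            p, d = x.promoter_anchor, x.distal_anchor
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{d.chrom}\t{d.start}\t{d.end}"
                f"\t{x.gene_id}\t{x.score:g}\n"
            )


# ---------------------------------------------------------------------------
# Count / expression matrices (TSV with header)


def read_count_matrix(path: str | Path, id_name: str = "peak_id") -> pd.DataFrame:
    """Read a TSV with a header of sample names and a first column of row
    ids.  Missing or non-numeric values are an error, not zero."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need an id column plus >= 1 sample column")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate id {dup!r}")
    values = df.iloc[:, 1:].copy()
    for col in values.columns:
        parsed = []
        for row, cell in enumerate(values[col]):
            try:
                # float() is correctly rounded; pandas' fast path is not
                value = float(cell)
                if np.isnan(value):
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric or missing value at row id "
                    f"{ids.iloc[row]!r}, column {col!r}"
                ) from None
            parsed.append(value)
        values[col] = np.array(parsed)
    values.index = pd.Index(ids, name=id_name)
    return values.astype(float)


def write_count_matrix(
    df: pd.DataFrame, path: str | Path, id_name: str = "peak_id"
) -> None:
    out = df.copy()
    out.index.name = id_name
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# JASPAR-style PWM text


def read_pwms(
    path: str | Path,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> dict[str, PWM]:
    """Parse JASPAR-style motif text.

    Each record is a ``>`` header line followed by four labeled rows
    (A, C, G, T) of non-negative counts or frequencies, optionally wrapped
    in brackets.  Counts are regularized with ``pseudocount`` added to every
    cell before per-column normalization.
    """
    motifs: dict[str, PWM] = {}
    current_id: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal current_id, rows
        if current_id is None:
            return
        missing = [b for b in "ACGT" if b not in rows]
        if missing:
            raise FormatError(
                f"{path}: motif {current_id}: missing row(s) {','.join(missing)}"
            )
        lengths = {len(rows[b]) for b in "ACGT"}
        if len(lengths) != 1:
            raise FormatError(
                f"{path}: motif {current_id}: rows of unequal length"
            )
        counts = np.array([rows[b] for b in "ACGT"])
        if (counts < 0).any():
            raise FormatError(f"{path}: motif {current_id}: negative value")
        motifs[current_id] = PWM.from_counts(
            current_id, counts, pseudocount=pseudocount, background=background
        )
        current_id, rows = None, {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
                rows = {}
                continue
            if current_id is None:
                raise FormatError(f"{path}:{lineno}: data before first '>' header")
            base = line[0].upper()
            if base not in "ACGT":
                raise FormatError(f"{path}:{lineno}: unexpected row label {line[0]!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                rows[base] = [float(tok) for tok in body.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    flush()
    return motifs


def write_pwms(pwms: Iterable[PWM], path: str | Path, scale: float = 100.0) -> None:
    """Write motifs as JASPAR-style count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for base, row in zip("ACGT", pwm.matrix * scale):
                cells = " ".join(f"{v:.4f}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# FASTA (per-peak sequences)


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header")
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Network serialization (graph-json / DOT)


def _validate_graph(graph: nx.DiGraph) -> None:
    for u, v in graph.edges:
        if u not in graph.nodes or v not in graph.nodes:  # pragma: no cover
            raise ValueError(f"edge ({u}, {v}) references absent node")


def write_network(graph: nx.DiGraph, path: str | Path, format: str = "graph-json") -> None:
    """Serialize a TF->target network.

    ``graph-json`` round-trips exactly (node-link JSON); ``dot`` is a plain
    Graphviz rendering for layout consumers.
    """
    _validate_graph(graph)
    if format == "graph-json":
        data = nx.node_link_data(graph, edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("digraph grn {\n")
            for n, attrs in sorted(graph.nodes(data=True)):
                expr = attrs.get("expression", 0.0)
                fh.write(f'  "{n}" [expression={expr:g}];\n')
            for u, v, attrs in sorted(graph.edges(data=True)):
                sc = attrs.get("site_count", 1)
                fh.write(f'  "{u}" -> "{v}" [site_count={sc}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.DiGraph:
    with open(path) as fh:
        data = json.load(fh)
    return nx.node_link_graph(data, edges="edges")
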