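"""Differential expression, set-overlap significance, group t-tests and the
LSC17 stemness score."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "GeneSetPair",
    "LSC17Weights",
    "read_expression",
    "fold_change_de",
    "overlap_significance",
    "group_ttest",
    "lsc17_score",
    "read_lsc17_weights",
    "default_lsc17_weights",
]


@dataclass
class ExpressionTable:
    """Genes x samples FPKM values with per-sample group labels."""

    fpkm: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ValueError("negative FPKM values")
        if self.fpkm.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if not self.group_of:
            self.group_of = {
                s: (s.rsplit("_", 1)[0] if "_" in s else s) for s in self.fpkm.columns
            }

    def samples_in(self, group: str) -> list[str]:
        hits = [s for s in self.fpkm.columns if self.group_of[s] == group]
        if not hits:
            raise ValueError(f"unknown group label {group!r}")
        return hits

    def group_means(self, group: str) -> pd.Series:
        return self.fpkm[self.samples_in(group)].mean(axis=1)


def read_expression(
    path: str | Path, group_of: dict[str, str] | None = None
) -> ExpressionTable:
    from regnet.genomic_io import read_count_matrix

    df = read_count_matrix(path, id_name="gene_id")
    return ExpressionTable(df, group_of or {})


@dataclass
class GeneSetPair:
    up: set[str]
    down: set[str]
    group_a: str
    group_b: str
    fold: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def fold_change_de(
    expr: ExpressionTable,
    group_a: str,
    group_b: str,
    fold: float = 4.0,
    pseudocount: float = 1.0,
) -> GeneSetPair:
    """Fold-change differential expression on pseudocounted group means.

    up: (meanA+pc)/(meanB+pc) >= fold; down: the reciprocal condition.
    """
    mean_a = expr.group_means(group_a) + pseudocount
    mean_b = expr.group_means(group_b) + pseudocount
    ratio = mean_a / mean_b
    up = set(ratio.index[ratio >= fold])
    down = set(ratio.index[1.0 / ratio >= fold])
    return GeneSetPair(up, down, group_a, group_b, fold)


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> float:
    """Hypergeometric upper-tail p-value for the overlap of two gene sets:
    P(X >= |A n B|) for X ~ Hypergeom(universe, |A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if len(a | b) > universe_size:
        raise ValueError(
            f"universe ({universe_size}) smaller than |A u B| ({len(a | b)})"
        )
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def group_ttest(
    expr: ExpressionTable, gene: str, group_a: str, group_b: str
) -> tuple[float, float]:
    """Classical two-sided Student's t-test (pooled variance) on one gene."""
    if gene not in expr.fpkm.index:
        raise ValueError(f"gene {gene!r} absent from expression table")
    xa = expr.fpkm.loc[gene, expr.samples_in(group_a)].to_numpy(dtype=float)
    xb = expr.fpkm.loc[gene, expr.samples_in(group_b)].to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 samples per group for a t-test")
    na, nb = len(xa), len(xb)
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = xa.mean() - xb.mean()
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled * (1 / na + 1 / nb))
    p = 2 * float(stats.t.sf(abs(t), na + nb - 2))
    return float(t), min(p, 1.0)


@dataclass
class LSC17Weights:
    """The 17-gene stemness signature weights, with a flagged CD34 entry."""

    weights: dict[str, float]
    cd34_gene: str = "CD34"

    def __post_init__(self) -> None:
        if len(self.weights) != 17:
            raise ValueError(f"expected 17 weights, got {len(self.weights)}")
        if self.cd34_gene not in self.weights:
            raise ValueError(f"weights lack the {self.cd34_gene} entry")

    def genes(self, exclude_cd34: bool = False) -> list[str]:
        return [
            g for g in self.weights if not (exclude_cd34 and g == self.cd34_gene)
        ]


def read_lsc17_weights(path: str | Path) -> LSC17Weights:
    """Read a two-column TSV (gene_id, weight) with header."""
    if not Path(path).exists():
        raise FileNotFoundError(f"weight file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "weight"]:
        raise ValueError("weight table must have columns gene_id, weight")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene rows in weight table")
    return LSC17Weights(dict(zip(df["gene_id"], df["weight"].astype(float))))


def default_lsc17_weights() -> LSC17Weights:
    """The canonical published 17-gene weights, shipped as package data."""
    ref = resources.files("regnet") / "data" / "lsc17_weights.tsv"
    with resources.as_file(ref) as path:
        return read_lsc17_weights(path)


def lsc17_score(
    expr: ExpressionTable,
    weights: LSC17Weights,
    exclude_cd34: bool = False,
    transform: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> pd.Series:
    """Weighted stemness score per sample: sum_i w_i * log2(FPKM_i + 1).

    ``exclude_cd34`` drops the CD34 term (16-gene variant); ``transform``
    replaces the default log2(x+1) on the FPKM sub-matrix.
    """
    genes = weights.genes(exclude_cd34=exclude_cd34)
    missing = [g for g in genes if g not in expr.fpkm.index]
    if missing:
        raise ValueError(f"expression table missing LSC17 genes: {missing}")
    sub = expr.fpkm.loc[genes]
    if expr.fpkm.index.get_indexer_for(genes).size != len(genes):  # pragma: no cover
        raise ValueError("duplicate LSC17 gene rows")
    values = np.log2(sub + 1.0) if transform is None else transform(sub)
    w = pd.Series({g: weights.weights[g] for g in genes})
    score = values.mul(w, axis=0).sum(axis=0)
    score.name = "lsc17_cd34_excluded" if exclude_cd34 else "lsc17"
    return score
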