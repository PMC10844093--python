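"""Synthetic regulatory study with a known planted program.

Generates a self-consistent cohort — peak intervals, peak sequences, TSS
annotation, promoter-contact records, tag-count matrices, per-base cleavage
profiles and FPKM expression tables — in the standard text formats the rest
of the package reads, together with a ground-truth record sufficient to
predict what every downstream stage should recover.

Model choices: negative-binomial tag counts (log-normal per-peak base mean
shared across samples, group-specific fold inflation at planted peaks),
Poisson per-base cleavage thinned by a depletion factor at occupied motif
bases, i.i.d. uniform background sequence with motif consensus instances
overwritten at recorded offsets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regnet.accessibility import TagCountMatrix
from regnet.genomic_io import (
    PWM,
    GenomicInterval,
    Interaction,
    TSSAnnotation,
    TSSRecord,
    write_bed,
    write_count_matrix,
    write_fasta,
    write_interactions,
    write_pwms,
    write_tss,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CutProfile",
    "Study",
    "simulate_study",
    "generate_study",
    "simulate_counts",
    "simulate_cut_profile",
    "write_cut_profiles",
    "read_cut_profiles",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study."""

    n_chromosomes: int = 2
    chrom_length: int = 4_000_000
    n_peaks: int = 1000
    peak_width: int = 400
    window: int = 2000
    n_tfs: int = 10
    n_targets: int = 200
    groups: tuple[tuple[str, int], ...] = (
        ("t69", 2),
        ("NPM1", 2),
        ("FLT3", 2),
        ("PBSC", 3),
    )
    accessibility_fold: float = 4.0
    expression_fold: float = 4.0
    footprint_depletion: float = 0.2
    mean_cuts_per_bp: float = 2.0
    nb_dispersion: float = 50.0
    seed: int = 0
    # planted-program shape
    n_edges: int = 60
    sites_per_edge: int = 2
    motif_length: int = 20
    n_common_motifs: int = 3
    n_common_peaks: int = 100
    n_other_specific: int = 80  # specific peaks per non-active AML group
    n_down_genes: int = 30
    n_proximal_peaks: int = 30
    decoy_interaction_fraction: float = 0.1
    base_count_log_mean: float = float(np.log(150.0))
    base_count_log_sd: float = 0.4
    expression_noise_sd: float = 0.0
    active_group: str = "t69"
    reference_group: str = "PBSC"

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_peaks, self.n_tfs, self.n_targets) < 1:
            raise ValueError("counts must be positive")
        if self.accessibility_fold < 1 or self.expression_fold < 1:
            raise ValueError("planted folds must be >= 1")
        if not (0 <= self.footprint_depletion <= 1):
            raise ValueError("footprint_depletion must lie in [0, 1]")
        if self.mean_cuts_per_bp <= 0 or self.nb_dispersion <= 0:
            raise ValueError("rates and dispersion must be positive")
        if self.window < self.peak_width:
            raise ValueError("window must be at least peak_width")
        if self.n_edges > self.n_targets:
            raise ValueError(
                f"cannot plant {self.n_edges} edges onto {self.n_targets} targets"
            )
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        for g in (self.active_group, self.reference_group):
            if g not in names:
                raise ValueError(f"group {g!r} not in groups")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs >= 1 sample")
        n_planted = self.n_edges * self.sites_per_edge
        needed = n_planted + self.n_common_peaks + self.n_proximal_peaks
        needed += self.n_other_specific * max(len(names) - 2, 0)
        if needed > self.n_peaks:
            raise ValueError(
                f"n_peaks={self.n_peaks} too small for the planted program "
                f"({needed} special peaks)"
            )

    @property
    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def group_of(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}


@dataclass
class OccupiedOccurrence:
    """A planted, protein-bound motif instance."""

    peak_id: str
    offset: int  # 0-based within the peak sequence
    motif_id: str
    groups: tuple[str, ...]  # sample groups in which the site is occupied


@dataclass
class PlantedEdge:
    tf: str
    target: str
    site_ids: tuple[str, ...]


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-running the pipeline."""

    tf_motif_map: dict[str, str]
    planted_edges: list[PlantedEdge]
    group_specific_peaks: dict[str, set[str]]
    planted_de_genes: dict[str, dict[str, set[str]]]  # group -> {"up", "down"}
    occupied: list[OccupiedOccurrence]
    peak_ids: list[str]
    motif_lengths: dict[str, int]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.planted_edges}

    def to_json(self, path: str | Path) -> None:
        data = {
            "tf_motif_map": self.tf_motif_map,
            "planted_edges": [
                {"tf": e.tf, "target": e.target, "site_ids": list(e.site_ids)}
                for e in self.planted_edges
            ],
            "group_specific_peaks": {
                g: sorted(s) for g, s in self.group_specific_peaks.items()
            },
            "planted_de_genes": {
                g: {k: sorted(v) for k, v in d.items()}
                for g, d in self.planted_de_genes.items()
            },
            "occupied": [
                {
                    "peak_id": o.peak_id,
                    "offset": o.offset,
                    "motif_id": o.motif_id,
                    "groups": list(o.groups),
                }
                for o in self.occupied
            ],
            "peak_ids": self.peak_ids,
            "motif_lengths": self.motif_lengths,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            tf_motif_map=data["tf_motif_map"],
            planted_edges=[
                PlantedEdge(e["tf"], e["target"], tuple(e["site_ids"]))
                for e in data["planted_edges"]
            ],
            group_specific_peaks={
                g: set(s) for g, s in data["group_specific_peaks"].items()
            },
            planted_de_genes={
                g: {k: set(v) for k, v in d.items()}
                for g, d in data["planted_de_genes"].items()
            },
            occupied=[
                OccupiedOccurrence(
                    o["peak_id"], o["offset"], o["motif_id"], tuple(o["groups"])
                )
                for o in data["occupied"]
            ],
            peak_ids=data["peak_ids"],
            motif_lengths=data["motif_lengths"],
        )


@dataclass
class CutProfile:
    """Per-base cleavage counts across a fixed window centered on a peak."""

    peak_id: str
    window_start: int
    cuts: np.ndarray

    def __post_init__(self) -> None:
        self.cuts = np.asarray(self.cuts, dtype=np.int64)
        if (self.cuts < 0).any():
            raise ValueError(f"negative cuts in profile {self.peak_id!r}")


@dataclass
class Study:
    """In-memory synthetic study; `write` emits every on-disk artifact."""

    config: SimConfig
    truth: GroundTruth
    peaks: list[GenomicInterval]
    sequences: dict[str, str]
    tss: TSSAnnotation
    interactions: list[Interaction]
    motifs: dict[str, PWM]
    counts: TagCountMatrix  # raw (unnormalized) tag counts
    expression: pd.DataFrame  # genes x samples, FPKM
    profiles: dict[str, dict[str, CutProfile]]  # group -> peak_id -> profile

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": outdir / "peaks.bed",
            "fasta": outdir / "peaks.fasta",
            "tss": outdir / "tss.bed",
            "interactions": outdir / "interactions.bedpe",
            "counts": outdir / "counts.tsv",
            "expression": outdir / "expression.tsv",
            "motifs": outdir / "motifs.jaspar",
            "tf_motifs": outdir / "tf_motifs.tsv",
            "groups": outdir / "groups.tsv",
            "truth": outdir / "truth.json",
        }
        write_bed(self.peaks, paths["peaks"])
        write_fasta(self.sequences, paths["fasta"])
        write_tss(self.tss, paths["tss"])
        write_interactions(self.interactions, paths["interactions"])
        write_count_matrix(self.counts.counts, paths["counts"])
        write_count_matrix(self.expression, paths["expression"], id_name="gene_id")
        write_pwms(self.motifs.values(), paths["motifs"])
        with open(paths["tf_motifs"], "w") as fh:
            fh.write("tf_gene_id\tmotif_id\n")
            for tf, motif in sorted(self.truth.tf_motif_map.items()):
                fh.write(f"{tf}\t{motif}\n")
        with open(paths["groups"], "w") as fh:
            fh.write("sample_id\tgroup\n")
            for s in self.counts.sample_ids:
                fh.write(f"{s}\t{self.counts.group_of[s]}\n")
        for group, profs in self.profiles.items():
            p = outdir / f"cuts_{group}.tsv"
            write_cut_profiles(profs, p)
            paths[f"cuts_{group}"] = p
        self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Cut-profile text format: peak_id <TAB> window_start <TAB> comma-joined ints


def write_cut_profiles(profiles: Mapping[str, CutProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in profiles:
            prof = profiles[pid]
            body = ",".join(map(str, prof.cuts.tolist()))
            fh.write(f"{prof.peak_id}\t{prof.window_start}\t{body}\n")


def read_cut_profiles(path: str | Path) -> dict[str, CutProfile]:
    out: dict[str, CutProfile] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            try:
                pid, start, body = line.split("\t")
                cuts = np.array(body.split(","), dtype=np.int64)
                out[pid] = CutProfile(pid, int(start), cuts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed profile line") from exc
    return out


# ---------------------------------------------------------------------------
# Generators


def _consensus_pwm(motif_id: str, consensus: str) -> PWM:
    """Near-deterministic PWM: consensus base count 97, others 1 each."""
    counts = np.full((4, len(consensus)), 1.0)
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        counts[index[b], j] = 97.0
    return PWM.from_counts(motif_id, counts)


def _random_consensus(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_counts(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TagCountMatrix:
    """Negative-binomial tag counts for every peak and sample.

    Per-peak base mean is log-normal and shared across samples; peaks
    specific to a sample's group have their mean multiplied by
    ``accessibility_fold``.  Dispersion follows the (mean, size) NB
    parameterization: var = mean + mean^2 / nb_dispersion.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    peak_ids = truth.peak_ids
    n = len(peak_ids)
    base = np.exp(
        rng.normal(config.base_count_log_mean, config.base_count_log_sd, size=n)
    )
    data = {}
    for sample in config.sample_ids:
        group = config.group_of[sample]
        specific = truth.group_specific_peaks.get(group, set())
        fold = np.array(
            [config.accessibility_fold if p in specific else 1.0 for p in peak_ids]
        )
        mean = base * fold
        # gamma-Poisson mixture == negative binomial with size nb_dispersion
        lam = rng.gamma(config.nb_dispersion, mean / config.nb_dispersion)
        data[sample] = rng.poisson(lam)
    df = pd.DataFrame(data, index=pd.Index(peak_ids, name="peak_id"), dtype=float)
    return TagCountMatrix(df, dict(config.group_of), normalized=False)


def simulate_cut_profile(
    peak: GenomicInterval,
    occupied: Sequence[tuple[int, int]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> CutProfile:
    """Poisson per-base cleavage over the window centered on the peak,
    thinned by ``footprint_depletion`` at occupied motif bases.

    ``occupied`` holds (peak-relative offset, motif length) pairs.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    window = config.window
    pad = (window - peak.length) // 2
    rate = np.full(window, config.mean_cuts_per_bp)
    for offset, length in occupied:
        lo, hi = offset + pad, offset + pad + length
        if offset < 0 or hi > window:
            raise ValueError(
                f"occupied occurrence at offset {offset} (length {length}) "
                f"outside the {window} bp window of peak {peak.id}"
            )
        rate[lo:hi] *= config.footprint_depletion
    cuts = rng.poisson(rate)
    return CutProfile(peak.id or "peak", peak.midpoint - window // 2, cuts)


def _layout_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[GenomicInterval], TSSAnnotation, dict[str, int]]:
    """Place genes and peaks on a regular interleaved grid, one TSS per
    gene, so nearest-TSS relations are unambiguous."""
    n_genes = config.n_tfs + config.n_targets
    gene_ids = [f"TF{i + 1:02d}" for i in range(config.n_tfs)] + [
        f"G{i + 1:03d}" for i in range(config.n_targets)
    ]
    entities: list[tuple[str, str]] = [("gene", g) for g in gene_ids]
    peak_ids = [f"peak{i + 1:05d}" for i in range(config.n_peaks)]
    entities += [("peak", p) for p in peak_ids]

    per_chrom = int(np.ceil(len(entities) / config.n_chromosomes))
    spacing = config.chrom_length // (per_chrom + 1)
    if spacing < max(config.window, 4000):
        raise ValueError(
            "chrom_length too small for the requested number of peaks/genes"
        )
    peaks: list[GenomicInterval] = []
    tss_records: list[TSSRecord] = []
    tss_position: dict[str, int] = {}
    for i, (kind, name) in enumerate(entities):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        slot = i // config.n_chromosomes
        pos = spacing * (slot + 1)
        if kind == "gene":
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            tss_records.append(TSSRecord(name, chrom, pos, strand))
            tss_position[name] = pos
        else:
            half = config.peak_width // 2
            peaks.append(
                GenomicInterval(chrom, pos - half, pos + half, name)
            )
    return peaks, TSSAnnotation(tss_records), tss_position


def simulate_study(config: SimConfig) -> Study:
    """Build the full synthetic study in memory (deterministic under seed)."""
    ss = np.random.SeedSequence([config.seed, 0])
    (
        rng_layout,
        rng_seq,
        rng_counts,
        rng_expr,
        rng_cuts,
        rng_misc,
    ) = [np.random.default_rng(s) for s in ss.spawn(6)]

    peaks, tss, tss_position = _layout_genome(config, rng_layout)
    peak_by_id = {p.id: p for p in peaks}
    peak_ids = [p.id for p in peaks]
    tf_ids = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    target_ids = [f"G{i + 1:03d}" for i in range(config.n_targets)]

    # --- motifs -----------------------------------------------------------
    motifs: dict[str, PWM] = {}
    consensi: dict[str, str] = {}
    seen: set[str] = set()
    motif_ids = [f"M_{tf}" for tf in tf_ids] + [
        f"M_COMMON{i + 1}" for i in range(config.n_common_motifs)
    ]
    for mid in motif_ids:
        while True:
            cons = _random_consensus(rng_seq, config.motif_length)
            if cons not in seen:
                seen.add(cons)
                break
        consensi[mid] = cons
        motifs[mid] = _consensus_pwm(mid, cons)
    tf_motif_map = {tf: f"M_{tf}" for tf in tf_ids}

    # --- planted program --------------------------------------------------
    aml_groups = [
        g for g in config.group_names if g != config.reference_group
    ]
    other_groups = [g for g in aml_groups if g != config.active_group]

    pool = list(peak_ids)
    n_sites = config.n_edges * config.sites_per_edge
    site_peaks = pool[:n_sites]
    cursor = n_sites
    group_specific: dict[str, set[str]] = {config.active_group: set(site_peaks)}
    for g in other_groups:
        group_specific[g] = set(pool[cursor : cursor + config.n_other_specific])
        cursor += config.n_other_specific
    common_peaks = pool[cursor : cursor + config.n_common_peaks]
    cursor += config.n_common_peaks
    proximal_peaks = pool[cursor : cursor + config.n_proximal_peaks]
    cursor += config.n_proximal_peaks

    # relocate proximal peaks next to a TSS so the distal filter has prey
    genes_cycle = list(tss_position)
    relocated: dict[str, GenomicInterval] = {}
    for i, pid in enumerate(proximal_peaks):
        gene = genes_cycle[i % len(genes_cycle)]
        rec = next(r for r in tss if r.gene_id == gene)
        half = config.peak_width // 2
        mid = tss_position[gene] + 300
        relocated[pid] = GenomicInterval(rec.chrom, mid - half, mid + half, pid)
    peaks = [relocated.get(p.id, p) for p in peaks]
    peak_by_id = {p.id: p for p in peaks}

    edge_targets = list(rng_misc.permutation(target_ids))[: config.n_edges]
    planted_edges: list[PlantedEdge] = []
    occupied: list[OccupiedOccurrence] = []
    site_iter = iter(site_peaks)
    margin = 10
    for i, target in enumerate(edge_targets):
        tf = tf_ids[i % config.n_tfs]
        sites = tuple(next(site_iter) for _ in range(config.sites_per_edge))
        planted_edges.append(PlantedEdge(tf, target, sites))
        for pid in sites:
            max_off = config.peak_width - config.motif_length - margin
            off = int(rng_misc.integers(margin, max_off + 1))
            occupied.append(
                OccupiedOccurrence(pid, off, tf_motif_map[tf], (config.active_group,))
            )
    for i, pid in enumerate(common_peaks):
        mid = f"M_COMMON{i % config.n_common_motifs + 1}"
        max_off = config.peak_width - config.motif_length - margin
        off = int(rng_misc.integers(margin, max_off + 1))
        occupied.append(
            OccupiedOccurrence(pid, off, mid, tuple(config.group_names))
        )

    down_pool = [t for t in target_ids if t not in set(edge_targets)]
    down_genes = set(down_pool[: config.n_down_genes])
    up_genes = set(edge_targets) if config.expression_fold > 1 else set()
    planted_de = {
        config.active_group: {
            "up": up_genes,
            "down": down_genes if config.expression_fold > 1 else set(),
        }
    }

    truth = GroundTruth(
        tf_motif_map=tf_motif_map,
        planted_edges=planted_edges,
        group_specific_peaks={
            g: (s if config.accessibility_fold > 1 else set())
            for g, s in group_specific.items()
        },
        planted_de_genes=planted_de,
        occupied=occupied,
        peak_ids=peak_ids,
        motif_lengths={m: len(pwm) for m, pwm in motifs.items()},
    )

    # --- sequences --------------------------------------------------------
    sequences: dict[str, str] = {}
    for pid in peak_ids:
        seq = _random_consensus(rng_seq, config.peak_width)
        sequences[pid] = seq
    for occ in occupied:
        cons = consensi[occ.motif_id]
        s = sequences[occ.peak_id]
        sequences[occ.peak_id] = (
            s[: occ.offset] + cons + s[occ.offset + len(cons) :]
        )

    # --- counts and expression -------------------------------------------
    counts = simulate_counts(truth, config, rng_counts)

    # stemness-signature genes ride along so scoring stages are exercisable
    from regnet.expression import default_lsc17_weights

    signature_genes = list(default_lsc17_weights().weights)
    expr_genes = tf_ids + target_ids + signature_genes
    base_expr = np.concatenate(
        [
            np.exp(rng_expr.normal(np.log(30.0), 0.3, size=config.n_tfs)),
            np.exp(rng_expr.normal(np.log(8.0), 0.5, size=config.n_targets)),
            np.exp(rng_expr.normal(np.log(15.0), 0.8, size=len(signature_genes))),
        ]
    )
    expr = {}
    active_samples = {
        s for s in config.sample_ids if config.group_of[s] == config.active_group
    }
    for sample in config.sample_ids:
        vals = base_expr.copy()
        if sample in active_samples and config.expression_fold > 1:
            for gi, g in enumerate(expr_genes):
                if g in up_genes:
                    vals[gi] *= config.expression_fold
                elif g in down_genes:
                    vals[gi] /= config.expression_fold
        if config.expression_noise_sd > 0:
            vals = vals * np.exp(
                rng_expr.normal(0, config.expression_noise_sd, size=len(vals))
            )
        expr[sample] = vals
    expression = pd.DataFrame(
        expr, index=pd.Index(expr_genes, name="gene_id")
    )

    # --- cut profiles per group ------------------------------------------
    occ_by_peak: dict[str, list[OccupiedOccurrence]] = {}
    for occ in occupied:
        occ_by_peak.setdefault(occ.peak_id, []).append(occ)
    pad = (config.window - config.peak_width) // 2
    profiles: dict[str, dict[str, CutProfile]] = {}
    for group in config.group_names:
        rate = np.full((config.n_peaks, config.window), config.mean_cuts_per_bp)
        for row, pid in enumerate(peak_ids):
            for occ in occ_by_peak.get(pid, ()):
                if group in occ.groups:
                    lo = occ.offset + pad
                    rate[row, lo : lo + config.motif_length] *= (
                        config.footprint_depletion
                    )
        cuts = rng_cuts.poisson(rate)
        profiles[group] = {
            pid: CutProfile(
                pid, peak_by_id[pid].midpoint - config.window // 2, cuts[row]
            )
            for row, pid in enumerate(peak_ids)
        }

    # --- interactions -----------------------------------------------------
    interactions: list[Interaction] = []
    tss_by_gene = {r.gene_id: r for r in tss}
    planted_site_set = set(site_peaks)
    for edge in planted_edges:
        rec = tss_by_gene[edge.target]
        prom = GenomicInterval(
            rec.chrom, max(rec.position - 500, 0), rec.position + 500
        )
        for pid in edge.site_ids:
            interactions.append(
                Interaction(
                    prom,
                    peak_by_id[pid],
                    edge.target,
                    float(5.0 + rng_misc.uniform(0, 5)),
                )
            )
    all_genes = list(tss_by_gene)
    for pid in peak_ids:
        if pid in planted_site_set:
            continue
        if rng_misc.uniform() < config.decoy_interaction_fraction:
            gene = all_genes[int(rng_misc.integers(0, len(all_genes)))]
            rec = tss_by_gene[gene]
            prom = GenomicInterval(
                rec.chrom, max(rec.position - 500, 0), rec.position + 500
            )
            interactions.append(
                Interaction(prom, peak_by_id[pid], gene, float(rng_misc.uniform(0, 2)))
            )

    return Study(
        config=config,
        truth=truth,
        peaks=peaks,
        sequences=sequences,
        tss=tss,
        interactions=interactions,
        motifs=motifs,
        counts=counts,
        expression=expression,
        profiles=profiles,
    )


def generate_study(
    config: SimConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Simulate a study and emit every artifact to ``outdir``.

    Identical config (including seed) produces byte-identical files.
    """
    study = simulate_study(config)
    paths = study.write(outdir)
    return paths, study.truth
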