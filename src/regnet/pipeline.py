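"""End-to-end orchestration: run every stage from one configuration, with a
manifest of output checksums and a log of all effective parameters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from regnet import accessibility as acc
from regnet import expression as xp
from regnet import footprinting as fpm
from regnet import grn as grnmod
from regnet.genomic_io import (
    read_bed,
    read_count_matrix,
    read_fasta,
    read_interactions,
    read_pwms,
    read_tss,
    write_bed,
    write_count_matrix,
    write_network,
)
from regnet.synthetic_data import read_cut_profiles

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]


@dataclass
class PipelineConfig:
    """Paths plus every tunable threshold of the pipeline."""

    # inputs
    peaks: str
    tss: str
    counts: str
    fasta: str
    motifs: str
    tf_motifs: str
    interactions: str
    expression: str
    cut_profiles: dict[str, str]  # group -> path
    outdir: str
    lsc17_weights: str | None = None
    groups: str | None = None  # optional sample -> group TSV
    # analysis groups
    aml_group: str = "t69"
    reference_group: str = "PBSC"
    contrast_a: str = "NPM1"
    contrast_b: str = "FLT3"
    # thresholds
    scale: float = 1e7
    min_dist: int = 1500
    rank_pseudocount: float = 1.0
    specific_fold: float = 4.0
    aml_fold: float = 2.0
    footprint_widths: tuple[int, ...] = fpm.DEFAULT_WIDTHS
    footprint_flank: int = 35
    footprint_score_min: float = 5.0
    rel_threshold: float = 0.8
    min_fpkm: float = 1.0
    max_nearest: int = 50_000
    min_interaction_score: float = 0.0
    de_fold: float = 4.0
    window: int = 2000
    seed: int = 0
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "footprint_widths" in raw:
            raw["footprint_widths"] = tuple(raw["footprint_widths"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["footprint_widths"] = list(self.footprint_widths)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_groups(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute every stage; returns the output manifest (file -> sha256).

    Any stage error aborts with the stage name and the propagated message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    log_lines: list[str] = [f"parameters: {json.dumps(config.to_dict(), sort_keys=True)}"]

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                log_lines.append(f"stage {name}: start")
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                log_lines.append(f"stage {name}: done")
                return False

        return _Ctx()

    group_of = _read_groups(config.groups) if config.groups else {}

    with stage("load"):
        peaks = read_bed(config.peaks)
        tss = read_tss(config.tss)
        counts_df = read_count_matrix(config.counts)
        matrix = acc.TagCountMatrix(counts_df, dict(group_of))
        sequences = read_fasta(config.fasta)
        pwms = read_pwms(config.motifs)
        interactions = read_interactions(config.interactions)
        expr = xp.read_expression(config.expression, dict(group_of) or None)
        tf_motifs_df = pd.read_csv(config.tf_motifs, sep="\t")
        tf_motifs = dict(zip(tf_motifs_df.iloc[:, 0], tf_motifs_df.iloc[:, 1]))

    with stage("normalize"):
        norm = acc.normalize_counts(matrix, scale=config.scale)
        path = outdir / "counts_normalized.tsv"
        write_count_matrix(norm.counts, path)
        outputs.append(path)

    with stage("distal-filter"):
        distal = acc.filter_distal(peaks, tss, min_dist=config.min_dist)
        distal_ids = {p.id for p in distal}
        path = outdir / "distal_peaks.bed"
        write_bed(distal, path)
        outputs.append(path)
        norm_distal = acc.TagCountMatrix(
            norm.counts.loc[[p for p in norm.peak_ids if p in distal_ids]],
            dict(norm.group_of),
            normalized=True,
        )

    with stage("cluster"):
        corr = acc.correlation_matrix(norm_distal)
        path = outdir / "correlation.tsv"
        corr.to_csv(path, sep="\t", float_format="%.10g")
        outputs.append(path)
        _, leaf_order = acc.hierarchical_cluster(corr)
        path = outdir / "leaf_order.txt"
        path.write_text("\n".join(leaf_order) + "\n")
        outputs.append(path)
        if config.figures:
            from regnet.plots import correlation_heatmap

            path = outdir / "correlation_heatmap.png"
            correlation_heatmap(corr, path)
            outputs.append(path)

    with stage("rank"):
        ranked = acc.rank_by_fold_change(
            norm_distal,
            config.contrast_a,
            config.contrast_b,
            pseudocount=config.rank_pseudocount,
        )
        path = outdir / "ranked_peaks.tsv"
        ranked.log2_fold_change.rename("log2_fold_change").to_csv(path, sep="\t")
        outputs.append(path)
        set_a, set_b = acc.specific_sites(ranked, fold=config.specific_fold)
        for s in (set_a, set_b):
            path = outdir / f"specific_sites_{s.group}.txt"
            path.write_text("\n".join(sorted(s.peak_ids)) + "\n")
            outputs.append(path)

    with stage("footprint"):
        profiles = {
            g: read_cut_profiles(p) for g, p in config.cut_profiles.items()
        }
        footprints_by_group: dict[str, list[fpm.Footprint]] = {}
        for group, profs in profiles.items():
            fps: list[fpm.Footprint] = []
            for pid in sorted(profs):
                if pid not in distal_ids:
                    continue
                fps.extend(
                    fpm.detect_footprints(
                        pid,
                        profs[pid].cuts,
                        widths=config.footprint_widths,
                        flank=config.footprint_flank,
                        score_min=config.footprint_score_min,
                    )
                )
            footprints_by_group[group] = fps
            path = outdir / f"footprints_{group}.tsv"
            with open(path, "w") as fh:
                fh.write("peak_id\tstart\tend\tscore\tn_cuts_inside\tn_cuts_flanks\n")
                for fp in fps:
                    fh.write(
                        f"{fp.peak_id}\t{fp.start}\t{fp.end}\t{fp.score:.4f}"
                        f"\t{fp.n_cuts_inside}\t{fp.n_cuts_flanks}\n"
                    )
            outputs.append(path)
        if config.figures:
            from regnet.plots import average_profile_plot

            for site_set in (set_a, set_b):
                averages = {}
                for group, profs in profiles.items():
                    ids = sorted(site_set.peak_ids & set(profs))
                    if ids:
                        averages[group] = acc.average_profile(
                            {p: profs[p].cuts for p in ids}, ids,
                            window=config.window,
                        )
                if averages:
                    path = outdir / f"average_profile_{site_set.group}_specific.png"
                    average_profile_plot(
                        averages, path,
                        title=f"{site_set.group}-specific sites (fold >= {site_set.fold:g})",
                    )
                    outputs.append(path)

    with stage("scan"):
        distal_seqs = {pid: sequences[pid] for pid in sorted(sequences) if pid in distal_ids}
        occurrences = fpm.scan_motifs(distal_seqs, pwms, rel_threshold=config.rel_threshold)
        path = outdir / "motif_occurrences.tsv"
        with open(path, "w") as fh:
            fh.write("peak_id\toffset\tstrand\tmotif_id\tlog_odds\n")
            for o in occurrences:
                fh.write(
                    f"{o.peak_id}\t{o.offset}\t{o.strand}\t{o.motif_id}\t{o.log_odds:.4f}\n"
                )
        outputs.append(path)

    peak_by_id = {p.id: p for p in peaks}
    motif_lengths = {m: len(p) for m, p in pwms.items()}
    window_offset = {
        pid: (config.window - peak_by_id[pid].length) // 2 for pid in peak_by_id
    }

    with stage("motif-score"):
        nonempty = {g: f for g, f in footprints_by_group.items() if f}
        if len(nonempty) >= 2:
            aml_specific = grnmod.aml_specific_peaks(
                norm, config.aml_group, config.reference_group, fold=config.aml_fold
            )
            background = distal_ids - aml_specific
            scores = fpm.motif_enrichment(
                nonempty,
                occurrences,
                background_peaks=background,
                motif_lengths=motif_lengths,
                window_offset=window_offset,
            )
            path = outdir / "motif_scores.tsv"
            scores.to_csv(path, sep="\t", float_format="%.6g")
            outputs.append(path)
            if config.figures:
                from regnet.plots import motif_score_heatmap

                path = outdir / "motif_scores.png"
                motif_score_heatmap(scores, path)
                outputs.append(path)
        else:
            log_lines.append("stage motif-score: skipped (fewer than 2 conditions with footprints)")

    with stage("assign"):
        peak_gene_map = grnmod.assign_peaks_to_genes(
            distal,
            interactions,
            tss,
            max_nearest=config.max_nearest,
            min_interaction_score=config.min_interaction_score,
        )
        path = outdir / "peak_gene_map.tsv"
        with open(path, "w") as fh:
            fh.write("peak_id\tgene_id\tevidence\tdistance\n")
            for pid in sorted(peak_gene_map.assignments):
                a = peak_gene_map[pid]
                fh.write(f"{pid}\t{a.gene_id}\t{a.evidence}\t{a.distance}\n")
        outputs.append(path)
        path = outdir / "unmapped_peaks.txt"
        path.write_text("\n".join(peak_gene_map.unmapped) + "\n")
        outputs.append(path)

    with stage("grn"):
        aml_specific = grnmod.aml_specific_peaks(
            norm, config.aml_group, config.reference_group, fold=config.aml_fold
        )
        aml_samples = [
            s for s, g in expr.group_of.items() if g == config.aml_group
        ]
        grn = grnmod.build_grn(
            aml_specific & distal_ids,
            footprints_by_group.get(config.aml_group, []),
            occurrences,
            peak_gene_map,
            tf_motifs,
            expr.fpkm,
            aml_samples,
            motif_lengths,
            window_offset=window_offset,
            min_fpkm=config.min_fpkm,
        )
        for fmt, name in (("graph-json", "grn.json"), ("dot", "grn.dot")):
            path = outdir / name
            write_network(grn.to_networkx(), path, format=fmt)
            outputs.append(path)
        path = outdir / "grn_edges.tsv"
        grn.edge_table().to_csv(path, sep="\t", index=False)
        outputs.append(path)

    with stage("de"):
        pair = xp.fold_change_de(
            expr, config.aml_group, config.reference_group, fold=config.de_fold
        )
        path = outdir / "de_genes.tsv"
        with open(path, "w") as fh:
            fh.write("gene_id\tdirection\n")
            for g in sorted(pair.up):
                fh.write(f"{g}\tup\n")
            for g in sorted(pair.down):
                fh.write(f"{g}\tdown\n")
        outputs.append(path)

    with stage("overlap"):
        pair_b = xp.fold_change_de(
            expr, config.contrast_a, config.reference_group, fold=config.de_fold
        )
        universe = expr.fpkm.shape[0]
        p_up = xp.overlap_significance(pair.up, pair_b.up, universe)
        p_down = xp.overlap_significance(pair.down, pair_b.down, universe)
        path = outdir / "overlap_pvalues.tsv"
        path.write_text(
            "comparison\tp_value\n"
            f"upregulated\t{p_up:.6g}\n"
            f"downregulated\t{p_down:.6g}\n"
        )
        outputs.append(path)

    with stage("ttest"):
        rows = []
        for gene in expr.fpkm.index:
            t, p = xp.group_ttest(
                expr, gene, config.aml_group, config.reference_group
            )
            rows.append((gene, t, p))
        path = outdir / "ttest.tsv"
        with open(path, "w") as fh:
            fh.write("gene_id\tt\tp\n")
            for gene, t, p in rows:
                fh.write(f"{gene}\t{t:.6g}\t{p:.6g}\n")
        outputs.append(path)

    with stage("lsc17"):
        weights = (
            xp.read_lsc17_weights(config.lsc17_weights)
            if config.lsc17_weights
            else xp.default_lsc17_weights()
        )
        have_all = all(g in expr.fpkm.index for g in weights.weights)
        if have_all:
            full = xp.lsc17_score(expr, weights)
            no_cd34 = xp.lsc17_score(expr, weights, exclude_cd34=True)
            path = outdir / "lsc17_scores.tsv"
            pd.DataFrame({"lsc17": full, "lsc17_no_cd34": no_cd34}).to_csv(
                path, sep="\t", float_format="%.10g"
            )
            outputs.append(path)
        else:
            log_lines.append(
                "stage lsc17: skipped (expression table lacks signature genes)"
            )

    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in outputs}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return manifest


def grn_recovery_from_study_dir(data_dir: str | Path):
    """Rebuild the TF network from an emitted synthetic study directory and
    score it against the planted truth.

    Consumes only the on-disk artifacts (plus truth.json); the leanest path
    through normalize -> specific sites -> footprints -> scan -> assign ->
    network.  Returns (RecoveryReport, GRN, GroundTruth).
    """
    from regnet.grn import (
        aml_specific_peaks,
        assign_peaks_to_genes,
        build_grn,
        grn_recovery_report,
    )
    from regnet.synthetic_data import GroundTruth

    data_dir = Path(data_dir)
    truth = GroundTruth.from_json(data_dir / "truth.json")
    peaks = read_bed(data_dir / "peaks.bed")
    tss = read_tss(data_dir / "tss.bed")
    interactions = read_interactions(data_dir / "interactions.bedpe")
    sequences = read_fasta(data_dir / "peaks.fasta")
    pwms = read_pwms(data_dir / "motifs.jaspar")
    group_of = _read_groups(data_dir / "groups.tsv")
    counts = read_count_matrix(data_dir / "counts.tsv")
    matrix = acc.TagCountMatrix(counts, dict(group_of))
    expr = xp.read_expression(data_dir / "expression.tsv", dict(group_of))
    tf_df = pd.read_csv(data_dir / "tf_motifs.tsv", sep="\t")
    tf_motifs = dict(zip(tf_df.iloc[:, 0], tf_df.iloc[:, 1]))

    # the active (planted) group is the one whose specific peaks carry edges
    aml_group = "t69"
    site_peaks = {s for e in truth.planted_edges for s in e.site_ids}
    for g, spec in truth.group_specific_peaks.items():
        if site_peaks and site_peaks <= set(spec):
            aml_group = g
            break

    norm = acc.normalize_counts(matrix)
    specific = aml_specific_peaks(norm, aml_group, "PBSC", fold=2.0)
    profiles = read_cut_profiles(data_dir / f"cuts_{aml_group}.tsv")
    footprints = []
    for pid in sorted(specific):
        footprints.extend(fpm.detect_footprints(pid, profiles[pid].cuts))
    occurrences = fpm.scan_motifs(
        {p: sequences[p] for p in sorted(specific)}, pwms
    )
    peak_gene_map = assign_peaks_to_genes(peaks, interactions, tss)
    peak_by_id = {p.id: p for p in peaks}
    window = len(next(iter(profiles.values())).cuts)
    window_offset = {
        pid: (window - peak_by_id[pid].length) // 2 for pid in peak_by_id
    }
    aml_samples = [s for s, g in group_of.items() if g == aml_group]
    grn = build_grn(
        specific,
        footprints,
        occurrences,
        peak_gene_map,
        tf_motifs,
        expr.fpkm,
        aml_samples,
        {m: len(p) for m, p in pwms.items()},
        window_offset=window_offset,
    )
    report = grn_recovery_report(grn, truth.edge_set())
    return report, grn, truth


def run_demo(seed: int, outdir: str | Path, **config_overrides) -> dict[str, str]:
    """Generate a synthetic study, run the pipeline on it and report how
    well the planted network was recovered."""
    from regnet.synthetic_data import SimConfig, generate_study

    outdir = Path(outdir)
    data_dir = outdir / "data"
    sim = SimConfig(seed=seed, **config_overrides)
    paths, truth = generate_study(sim, data_dir)
    cfg = PipelineConfig(
        peaks=str(paths["peaks"]),
        tss=str(paths["tss"]),
        counts=str(paths["counts"]),
        fasta=str(paths["fasta"]),
        motifs=str(paths["motifs"]),
        tf_motifs=str(paths["tf_motifs"]),
        interactions=str(paths["interactions"]),
        expression=str(paths["expression"]),
        cut_profiles={
            g: str(paths[f"cuts_{g}"]) for g in sim.group_names
        },
        groups=str(paths["groups"]),
        outdir=str(outdir / "results"),
        aml_group=sim.active_group,
        reference_group=sim.reference_group,
        contrast_a="NPM1" if "NPM1" in sim.group_names else sim.active_group,
        contrast_b="FLT3" if "FLT3" in sim.group_names else sim.reference_group,
        window=sim.window,
        seed=seed,
    )
    manifest = run_pipeline(cfg)
    from regnet.genomic_io import read_network
    from regnet.grn import GRN, grn_recovery_report

    grn = GRN.from_networkx(read_network(outdir / "results" / "grn.json"))
    report = grn_recovery_report(grn, truth.edge_set())
    (outdir / "results" / "recovery.txt").write_text(str(report) + "\n")
    return manifest
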