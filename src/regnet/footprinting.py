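"""Digital footprint detection, PWM scanning and motif enrichment.

Footprints are modeled as binomial depletion: conditional on the total cut
count N over a candidate interval plus symmetric flanks, the count n inside
the interval is Binomial(N, p0) under no protection, with p0 the interval's
share of the span.  Occupancy shows up as a small lower-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regnet.genomic_io import PWM

__all__ = [
    "Footprint",
    "MotifOccurrence",
    "DEFAULT_WIDTHS",
    "footprint_statistic",
    "detect_footprints",
    "scan_motifs",
    "motif_enrichment",
    "condition_specific_motifs",
]

DEFAULT_WIDTHS: tuple[int, ...] = (11, 15, 19, 23, 27, 31)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class Footprint:
    """A protected interval within a cut-profile window.

    Coordinates are window-relative, 0-based half-open.
    """

    peak_id: str
    start: int
    end: int
    score: float  # -log10 binomial p-value
    n_cuts_inside: int
    n_cuts_flanks: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("footprint end must exceed start")
        if self.score < 0 or self.n_cuts_inside < 0 or self.n_cuts_flanks < 0:
            raise ValueError("negative footprint score or counts")


@dataclass(frozen=True)
class MotifOccurrence:
    peak_id: str
    offset: int  # 0-based within the peak sequence
    strand: str
    motif_id: str
    log_odds: float


def footprint_statistic(
    cuts: np.ndarray, start: int, width: int, flank: int
) -> tuple[float, float]:
    """Lower-tail binomial depletion test for one candidate interval.

    n = cuts inside [start, start+width); N = cuts in the interval plus both
    flanks; p0 = width/(width + 2*flank).  Returns (p_value, -log10 p).
    """
    cuts = np.asarray(cuts)
    if start - flank < 0 or start + width + flank > len(cuts):
        raise ValueError("footprint span (with flanks) outside the window")
    n = int(cuts[start : start + width].sum())
    n_flanks = int(cuts[start - flank : start].sum()) + int(
        cuts[start + width : start + width + flank].sum()
    )
    big_n = n + n_flanks
    p0 = width / (width + 2 * flank)
    p_value = float(stats.binom.cdf(n, big_n, p0)) if big_n > 0 else 1.0
    p_value = min(max(p_value, np.nextafter(0, 1)), 1.0)
    return p_value, float(-np.log10(p_value))


def _sliding_pvalues(
    cuts: np.ndarray, width: int, flank: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized lower-tail p-values for every start of one width.

    Returns (starts, p_values, inside_counts)."""
    window = len(cuts)
    csum = np.concatenate([[0], np.cumsum(cuts)])
    starts = np.arange(flank, window - width - flank + 1)
    inside = csum[starts + width] - csum[starts]
    span = csum[starts + width + flank] - csum[starts - flank]
    p0 = width / (width + 2 * flank)
    with np.errstate(divide="ignore"):
        pvals = stats.binom.cdf(inside, span, p0)
    pvals = np.where(span > 0, pvals, 1.0)
    return starts, np.clip(pvals, np.nextafter(0, 1), 1.0), inside


def detect_footprints(
    peak_id: str,
    cuts: np.ndarray,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    flank: int = 35,
    score_min: float = 5.0,
) -> list[Footprint]:
    """Scan every width over the window and keep a greedy non-overlapping
    set of footprints with score >= score_min, sorted by position."""
    cuts = np.asarray(cuts)
    if len(cuts) <= max(widths) + 2 * flank:
        raise ValueError("profile shorter than max width + 2*flank")
    candidates: list[tuple[float, int, int, int, int]] = []
    total = int(cuts.sum())
    for width in sorted(widths):
        starts, pvals, inside = _sliding_pvalues(cuts, width, flank)
        scores = -np.log10(pvals)
        hit = scores >= score_min
        for s, sc, n_in in zip(starts[hit], scores[hit], inside[hit]):
            candidates.append((float(sc), int(s), width, int(n_in), total))
    # greedy: best score first; ties resolved by position then width
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[Footprint] = []
    occupied: list[tuple[int, int]] = []
    for score, start, width, n_in, _ in candidates:
        end = start + width
        if any(start < e and b < end for b, e in occupied):
            continue
        n_flanks = int(
            cuts[start - flank : start].sum() + cuts[end : end + flank].sum()
        )
        accepted.append(
            Footprint(peak_id, start, end, score, n_in, n_flanks)
        )
        occupied.append((start, end))
    accepted.sort(key=lambda f: f.start)
    return accepted


# ---------------------------------------------------------------------------
# PWM scanning


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid character {exc.args[0]!r}")


def _scan_one_strand(
    encoded: np.ndarray, score_table: np.ndarray
) -> np.ndarray:
    """Log-odds at every offset for one PWM orientation; N scores -inf."""
    length = score_table.shape[1]
    n_offsets = len(encoded) - length + 1
    if n_offsets <= 0:
        return np.empty(0)
    idx = np.arange(n_offsets)[:, None] + np.arange(length)[None, :]
    return score_table[encoded[idx], np.arange(length)[None, :]].sum(axis=1)


def scan_motifs(
    sequences: Mapping[str, str],
    pwms: Mapping[str, PWM] | Iterable[PWM],
    rel_threshold: float = 0.8,
) -> list[MotifOccurrence]:
    """Scan peak sequences with PWMs on both strands.

    The reported log-odds is sum(log2(p_base/background)); an occurrence is
    kept when its score reaches ``rel_threshold`` times the maximum
    achievable log-odds of that PWM.  Minus-strand hits are scored on the
    reverse complement; their offset refers to the forward sequence.
    """
    if isinstance(pwms, Mapping):
        pwms = list(pwms.values())
    out: list[MotifOccurrence] = []
    for peak_id, seq in sequences.items():
        encoded = _encode(seq.upper())
        for pwm in pwms:
            threshold = rel_threshold * pwm.max_score
            for strand, oriented in (("+", pwm), ("-", pwm.reverse_complement())):
                table = np.vstack([oriented.log_odds, np.full(len(pwm), -np.inf)])
                scores = _scan_one_strand(encoded, table)
                for off in np.nonzero(scores >= threshold)[0]:
                    out.append(
                        MotifOccurrence(
                            peak_id, int(off), strand, pwm.motif_id, float(scores[off])
                        )
                    )
    out.sort(key=lambda o: (o.peak_id, o.offset, o.motif_id, o.strand))
    return out


# ---------------------------------------------------------------------------
# Motif enrichment over footprints


def _footprint_overlaps_motif(
    fp_start: int, fp_end: int, occ_start: int, occ_end: int
) -> bool:
    return fp_start < occ_end and occ_start < fp_end


def motif_enrichment(
    footprints_by_condition: Mapping[str, Sequence[Footprint]],
    occurrences: Sequence[MotifOccurrence],
    background_peaks: set[str],
    motif_lengths: Mapping[str, int],
    window_offset: Mapping[str, int] | int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Motif x condition table of log2 enrichment scores.

    For motif m in condition c, f_obs is the pseudocounted fraction of
    condition-c footprints overlapping an occurrence of m; f_bg is the same
    fraction computed over the condition's footprints that fall in
    ``background_peaks``; score = log2(f_obs/f_bg).  Computing the
    background within each condition keeps the pseudocounted fractions
    comparable when conditions have different footprint counts.

    ``window_offset`` converts motif offsets (peak-relative) to footprint
    coordinates (window-relative): occurrence window position = peak offset
    + window_offset[peak].  Pass an int when the offset is shared.
    """
    for cond, fps in footprints_by_condition.items():
        if not fps:
            raise ValueError(f"empty footprint set for condition {cond!r}")

    def offset_of(peak_id: str) -> int:
        if isinstance(window_offset, int):
            return window_offset
        return window_offset[peak_id]

    occ_by_peak: dict[str, list[tuple[int, int, str]]] = {}
    for occ in occurrences:
        span = (
            occ.offset + offset_of(occ.peak_id),
            occ.offset + offset_of(occ.peak_id) + motif_lengths[occ.motif_id],
        )
        occ_by_peak.setdefault(occ.peak_id, []).append((*span, occ.motif_id))

    motifs = sorted(motif_lengths)

    def hit_fraction(fps: Sequence[Footprint], motif: str) -> float:
        hits = 0
        for fp in fps:
            for s, e, m in occ_by_peak.get(fp.peak_id, ()):
                if m == motif and _footprint_overlaps_motif(fp.start, fp.end, s, e):
                    hits += 1
                    break
        return (hits + pseudocount) / (len(fps) + pseudocount)

    table = {}
    for cond, fps in footprints_by_condition.items():
        bg_fps = [fp for fp in fps if fp.peak_id in background_peaks]
        col = {}
        for motif in motifs:
            f_obs = hit_fraction(fps, motif)
            f_bg = hit_fraction(bg_fps, motif)
            col[motif] = float(np.log2(f_obs / f_bg))
        table[cond] = col
    df = pd.DataFrame(table)
    df.index.name = "motif_id"
    return df


def condition_specific_motifs(
    scores: pd.DataFrame,
    condition: str,
    reference: str,
    min_score: float = 1.0,
    max_reference_score: float = float(np.log2(1.25)),
) -> list[str]:
    """Motifs scoring >= min_score in the condition and below
    max_reference_score in the reference (healthy) condition."""
    sel = (scores[condition] >= min_score) & (scores[reference] < max_reference_score)
    return sorted(scores.index[sel])
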