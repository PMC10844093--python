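import math
from fractions import Fraction

import numpy as np
import pytest

from regnet import footprinting as fpm
from regnet.genomic_io import PWM


def binom_cdf_exact(n, N, p0_frac):
    """Independent oracle: exact rational lower-tail binomial CDF."""
    p = Fraction(*p0_frac)
    total = Fraction(0)
    for k in range(0, n + 1):
        total += (
            Fraction(math.comb(N, k)) * p**k * (1 - p) ** (N - k)
        )
    return float(total)


def _cuts_with(n_inside, n_left, n_right, width, flank, start=None):
    """Build a window realizing given inside/flank counts."""
    start = flank if start is None else start
    cuts = np.zeros(start + width + flank, dtype=int)
    # spread counts evenly enough; exact placement is irrelevant to the stat
    cuts[start - flank] = n_left
    cuts[start] = n_inside
    cuts[start + width] = n_right
    return cuts, start


class TestFootprintStatistic:
    def test_closed_form_zero_inside(self):
        # width 20, flank 20 (p0=1/3), N=100, n=0 -> p=(2/3)^100
        cuts, start = _cuts_with(0, 50, 50, width=20, flank=20)
        p, score = fpm.footprint_statistic(cuts, start, 20, 20)
        assert p == pytest.approx((2 / 3) ** 100, rel=1e-10)
        assert score == pytest.approx(100 * np.log10(1.5), abs=1e-8)

    def test_all_cuts_inside_no_depletion(self):
        cuts, start = _cuts_with(80, 0, 0, width=20, flank=20)
        p, score = fpm.footprint_statistic(cuts, start, 20, 20)
        assert p == 1.0
        assert score == 0.0

    def test_empty_span_p_one(self):
        cuts = np.zeros(200, dtype=int)
        p, score = fpm.footprint_statistic(cuts, 50, 20, 30)
        assert p == 1.0 and score == 0.0

    def test_span_outside_window_rejected(self):
        cuts = np.zeros(100, dtype=int)
        with pytest.raises(ValueError, match="outside"):
            fpm.footprint_statistic(cuts, 5, 20, 20)

    @pytest.mark.parametrize(
        "p0_frac,width,flank",
        [((1, 5), 20, 40), ((1, 3), 20, 20), ((1, 2), 20, 10)],
    )
    def test_matches_exact_binomial_oracle(self, p0_frac, width, flank):
        for N in (0, 1, 2, 5, 17, 60, 128, 200):
            step = max(1, N // 7)
            for n in range(0, N + 1, step):
                cuts, start = _cuts_with(n, (N - n) // 2, N - n - (N - n) // 2,
                                         width, flank)
                p, _ = fpm.footprint_statistic(cuts, start, width, flank)
                assert p == pytest.approx(
                    binom_cdf_exact(n, N, p0_frac), abs=1e-10
                ), (N, n, p0_frac)


class TestDetectFootprints:
    def test_planted_zero_depletion_detected(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(100):
            cuts = rng.poisson(2.0, 2000)
            cuts[1000:1012] = 0
            fps = fpm.detect_footprints("p", cuts)
            hits += any(
                fp.start < 1012 and 1000 < fp.end and fp.score > 5 for fp in fps
            )
        assert hits >= 95

    def test_non_overlapping_by_construction(self):
        rng = np.random.default_rng(3)
        rate = np.full(2000, 2.0)
        for lo in (300, 700, 1100):
            rate[lo : lo + 15] = 0.05
        for _ in range(20):
            fps = fpm.detect_footprints("p", rng.poisson(rate), score_min=2.0)
            spans = sorted((f.start, f.end) for f in fps)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_sorted_by_position(self):
        rng = np.random.default_rng(4)
        rate = np.full(2000, 2.0)
        rate[500:515] = 0
        rate[1500:1515] = 0
        fps = fpm.detect_footprints("p", rng.poisson(rate))
        starts = [f.start for f in fps]
        assert starts == sorted(starts)

    def test_profile_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fpm.detect_footprints("p", np.zeros(90, dtype=int))

    def test_power_monotone_in_depletion(self):
        # deeper depletion (0.1) must detect at least as often as 0.5
        def rate_profile(depletion, rng):
            rate = np.full(2000, 2.0)
            rate[1000:1014] *= depletion
            return rng.poisson(rate)

        det = {}
        for depletion in (0.1, 0.5):
            hits = 0
            for seed in range(60):  # paired seeds
                rng = np.random.default_rng(1000 + seed)
                fps = fpm.detect_footprints("p", rate_profile(depletion, rng))
                hits += any(fp.start < 1014 and 1000 < fp.end for fp in fps)
            det[depletion] = hits
        assert det[0.1] >= det[0.5]


def _perfect_pwm(consensus):
    counts = np.zeros((4, len(consensus)))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        counts[idx[b], j] = 100.0
    return PWM.from_counts("M_" + consensus, counts)


def brute_force_scan(sequences, pwms, rel_threshold=0.8):
    """Independent oracle: enumerate every offset and strand in python."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = set()
    for pid, seq in sequences.items():
        for pwm in pwms:
            L = len(pwm)
            lo = pwm.log_odds
            thr = rel_threshold * pwm.max_score
            for strand in "+-":
                for off in range(len(seq) - L + 1):
                    sub = seq[off : off + L]
                    if strand == "-":
                        sub = "".join(comp[b] for b in reversed(sub))
                    score = 0.0
                    for j, b in enumerate(sub):
                        if b == "N":
                            score = -np.inf
                            break
                        score += lo[idx[b], j]
                    if score >= thr:
                        out.add((pid, off, strand, pwm.motif_id, round(score, 6)))
    return out


class TestScanMotifs:
    def test_perfect_match_plus_strand(self):
        pwm = _perfect_pwm("ACGT")
        occs = fpm.scan_motifs({"p": "ACGT"}, [pwm])
        plus = [o for o in occs if o.strand == "+"]
        assert len(plus) == 1
        assert plus[0].offset == 0
        assert plus[0].log_odds == pytest.approx(pwm.max_score)

    def test_reverse_complement_hit(self):
        pwm = _perfect_pwm("AACC")
        occs = fpm.scan_motifs({"p": "GGTT"}, [pwm])
        assert [(o.offset, o.strand) for o in occs] == [(0, "-")]
        assert occs[0].log_odds == pytest.approx(pwm.max_score)

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid character"):
            fpm.scan_motifs({"p": "ACGU"}, [_perfect_pwm("ACGT")])

    def test_n_never_matches(self):
        occs = fpm.scan_motifs({"p": "ANGT"}, [_perfect_pwm("ACGT")])
        assert [o for o in occs if o.strand == "+"] == []

    def test_against_brute_force(self, rng):
        pwms = [
            _perfect_pwm("ACGTAC"),
            PWM.from_counts(
                "Mrand", rng.integers(0, 20, size=(4, 7)).astype(float)
            ),
        ]
        sequences = {
            f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
            for i in range(50)
        }
        got = {
            (o.peak_id, o.offset, o.strand, o.motif_id, round(o.log_odds, 6))
            for o in fpm.scan_motifs(sequences, pwms, rel_threshold=0.8)
        }
        assert got == brute_force_scan(sequences, pwms, rel_threshold=0.8)

    def test_rc_invariance(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        pwms = [PWM.from_counts(
            "M", rng.integers(0, 15, size=(4, 6)).astype(float)
        )]
        seqs = {
            f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
            for i in range(10)
        }
        rc_seqs = {
            k: "".join(comp[b] for b in reversed(v)) for k, v in seqs.items()
        }
        fwd = fpm.scan_motifs(seqs, pwms, rel_threshold=0.7)
        rev = fpm.scan_motifs(rc_seqs, pwms, rel_threshold=0.7)
        flip = {"+": "-", "-": "+"}
        mapped = {
            (o.peak_id, len(seqs[o.peak_id]) - 6 - o.offset, flip[o.strand],
             round(o.log_odds, 9))
            for o in fwd
        }
        got = {
            (o.peak_id, o.offset, o.strand, round(o.log_odds, 9)) for o in rev
        }
        assert mapped == got


class TestMotifEnrichment:
    def _fp(self, pid, start=0, end=10):
        return fpm.Footprint(pid, start, end, 6.0, 1, 50)

    def test_forced_arithmetic_score_one(self):
        # all: 5 footprints, 2 overlapping -> f_obs = (2+1)/(5+1) = 0.5
        # background subset: 3 footprints, 0 overlap -> f_bg = (0+1)/(3+1)
        occ = [fpm.MotifOccurrence("pkA", 2, "+", "M", 5.0),
               fpm.MotifOccurrence("pkB", 2, "+", "M", 5.0)]
        fps = [self._fp("pkA"), self._fp("pkB")] + [
            self._fp(f"bg{i}") for i in range(3)
        ]
        table = fpm.motif_enrichment(
            {"aml": fps},
            occ,
            background_peaks={"bg0", "bg1", "bg2"},
            motif_lengths={"M": 6},
        )
        assert table.loc["M", "aml"] == pytest.approx(1.0)

    def test_equal_fractions_score_zero(self):
        occ = [fpm.MotifOccurrence("pkA", 2, "+", "M", 5.0)]
        fps = [self._fp("pkA"), self._fp("pkB")]
        table = fpm.motif_enrichment(
            {"aml": fps},
            occ,
            background_peaks={"pkA", "pkB"},
            motif_lengths={"M": 6},
        )
        assert table.loc["M", "aml"] == pytest.approx(0.0)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="empty footprint set"):
            fpm.motif_enrichment(
                {"aml": []}, [], background_peaks=set(), motif_lengths={}
            )

    def test_planted_motifs_condition_specific(self):
        """Motifs planted in group-specific peaks score high in that group
        and near zero in the reference, across seeded replicates."""
        from regnet.synthetic_data import SimConfig, simulate_study

        passes = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_peaks=200, n_tfs=4, n_targets=40, n_edges=16,
                sites_per_edge=2, n_common_peaks=40, n_other_specific=0,
                n_proximal_peaks=0, groups=(("t69", 2), ("PBSC", 3)),
                chrom_length=2_000_000, seed=900 + seed,
            )
            study = simulate_study(cfg)
            pad = (cfg.window - cfg.peak_width) // 2
            fps_by_cond = {}
            for group in ("t69", "PBSC"):
                fps = []
                for pid, prof in study.profiles[group].items():
                    fps.extend(fpm.detect_footprints(pid, prof.cuts))
                fps_by_cond[group] = fps
            occurrences = fpm.scan_motifs(study.sequences, study.motifs)
            specific = study.truth.group_specific_peaks["t69"]
            background = set(study.truth.peak_ids) - specific
            table = fpm.motif_enrichment(
                fps_by_cond, occurrences, background_peaks=background,
                motif_lengths=study.truth.motif_lengths, window_offset=pad,
            )
            tf_motifs = set(study.truth.tf_motif_map.values())
            ok = all(
                table.loc[m, "t69"] >= 1.0 and table.loc[m, "PBSC"] < 0.32
                for m in tf_motifs
            )
            passes += ok
        assert passes >= n_seeds - 1

    def test_condition_specific_selector(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"aml": [1.5, 0.4, 2.0], "PBSC": [0.1, 0.1, 1.0]},
            index=["m1", "m2", "m3"],
        )
        assert fpm.condition_specific_motifs(scores, "aml", "PBSC") == ["m1"]
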