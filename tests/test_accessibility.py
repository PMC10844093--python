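import numpy as np
import pandas as pd
import pytest

from regnet import accessibility as acc
from regnet.genomic_io import GenomicInterval, TSSAnnotation, TSSRecord

from conftest import make_matrix


class TestNormalize:
    def test_proportional_scaling(self):
        m = make_matrix([[2], [3], [5]], ["s1"])
        out = acc.normalize_counts(m, scale=100)
        np.testing.assert_allclose(out.counts["s1"].values, [20, 30, 50])
        assert out.normalized

    def test_double_normalization_guard(self):
        m = make_matrix([[1], [2]], ["s1"])
        out = acc.normalize_counts(m)
        with pytest.raises(ValueError, match="already normalized"):
            acc.normalize_counts(out)

    def test_zero_total_sample_named(self):
        m = make_matrix([[1, 0], [2, 0]], ["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            acc.normalize_counts(m)

    def test_columns_sum_to_scale(self, rng):
        m = make_matrix(rng.exponential(10, (30, 4)) + 0.1, list("abcd"))
        out = acc.normalize_counts(m, scale=1e6)
        np.testing.assert_allclose(out.counts.sum(axis=0).values, 1e6, atol=1e-6)


class TestFilterDistal:
    def test_close_peak_removed(self):
        peaks = [GenomicInterval("chr1", 10_000, 10_400, "pk")]
        tss = TSSAnnotation([TSSRecord("G", "chr1", 10_250)])
        assert acc.filter_distal(peaks, tss) == []

    def test_boundary_is_inclusive(self):
        # midpoint 10_200, TSS at 11_700 -> distance exactly 1500: retained
        peaks = [GenomicInterval("chr1", 10_000, 10_400, "pk")]
        tss = TSSAnnotation([TSSRecord("G", "chr1", 11_700)])
        assert len(acc.filter_distal(peaks, tss, min_dist=1500)) == 1
        assert len(acc.filter_distal(peaks, tss, min_dist=1501)) == 0

    def test_tss_free_chromosome_retained(self):
        peaks = [GenomicInterval("chrUn", 0, 400, "pk")]
        tss = TSSAnnotation([TSSRecord("G", "chr1", 0)])
        assert len(acc.filter_distal(peaks, tss)) == 1

    def test_against_brute_force(self, rng):
        peaks = [
            GenomicInterval(
                f"chr{rng.integers(1, 4)}", int(s), int(s) + 400, f"pk{i}"
            )
            for i, s in enumerate(rng.integers(0, 200_000, size=200))
        ]
        tss = TSSAnnotation(
            [
                TSSRecord(f"g{i}", f"chr{rng.integers(1, 4)}", int(p))
                for i, p in enumerate(rng.integers(0, 200_000, size=200))
            ]
        )
        got = {p.id for p in acc.filter_distal(peaks, tss, min_dist=1500)}
        expected = set()
        for p in peaks:
            dists = [
                abs(r.position - p.midpoint) for r in tss if r.chrom == p.chrom
            ]
            if not dists or min(dists) >= 1500:
                expected.add(p.id)
        assert got == expected


class TestCorrelation:
    def test_duplicate_sample_r_one(self):
        m = make_matrix([[1, 1], [5, 5], [9, 9]], ["a", "a2"], normalized=True)
        corr = acc.correlation_matrix(m, log_transform=False)
        assert corr.loc["a", "a2"] == pytest.approx(1.0)

    def test_reflection_r_minus_one(self):
        x = np.array([1.0, 2.0, 3.0])
        m = make_matrix(np.column_stack([x, 2 * x.mean() - x]), ["x", "refl"],
                        normalized=True)
        corr = acc.correlation_matrix(m, log_transform=False)
        assert corr.loc["x", "refl"] == pytest.approx(-1.0)

    def test_against_pearson_formula(self, rng):
        vals = rng.exponential(50, size=(5, 3))
        m = make_matrix(vals, ["a", "b", "c"], normalized=True)
        corr = acc.correlation_matrix(m, log_transform=True)
        logv = np.log2(vals + 1)
        for i, si in enumerate(["a", "b", "c"]):
            for j, sj in enumerate(["a", "b", "c"]):
                x, y = logv[:, i], logv[:, j]
                r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert corr.loc[si, sj] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_sample_named(self):
        m = make_matrix([[1, 3], [1, 5]], ["flat", "ok"], normalized=True)
        with pytest.raises(ValueError, match="flat"):
            acc.correlation_matrix(m, log_transform=False)

    def test_diagonal_exactly_one(self, rng):
        m = make_matrix(rng.exponential(9, (20, 5)), list("abcde"), normalized=True)
        corr = acc.correlation_matrix(m)
        assert (np.diag(corr.values) == 1.0).all()
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self, rng):
        base = rng.exponential(20, size=30)
        vals = np.column_stack([base, base, rng.exponential(20, 30)])
        m = make_matrix(vals, ["dup1", "dup2", "other"], normalized=True)
        corr = acc.correlation_matrix(m, log_transform=False)
        linkage, _ = acc.hierarchical_cluster(corr)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(linkage[0, 0]), int(linkage[0, 1])}
        assert merged == {0, 1}  # dup1, dup2 in sorted sample order

    def test_planted_groups_merge_within_first(self, rng):
        sig_a = rng.exponential(30, 100)
        sig_b = rng.exponential(30, 100)
        noise = lambda: rng.normal(0, 1, 100)
        vals = np.column_stack(
            [np.abs(sig_a + noise()), np.abs(sig_a + noise()),
             np.abs(sig_b + noise()), np.abs(sig_b + noise())]
        )
        m = make_matrix(vals, ["a1", "a2", "b1", "b2"], normalized=True)
        corr = acc.correlation_matrix(m, log_transform=False)
        linkage, _ = acc.hierarchical_cluster(corr)
        first_two = [
            {int(linkage[i, 0]), int(linkage[i, 1])} for i in range(2)
        ]
        assert {0, 1} in first_two and {2, 3} in first_two

    def test_leaf_order_deterministic(self, rng):
        vals = rng.exponential(10, (40, 6))
        m = make_matrix(vals, list("fedcba"), normalized=True)
        corr = acc.correlation_matrix(m)
        _, order1 = acc.hierarchical_cluster(corr)
        _, order2 = acc.hierarchical_cluster(corr)
        assert order1 == order2


class TestRankByFoldChange:
    def _matrix(self):
        # peak p1: meanA 40, meanB 10
        return make_matrix(
            [[40, 40, 10, 10], [10, 10, 10, 10], [5, 5, 40, 40]],
            ["A_1", "A_2", "B_1", "B_2"],
            peaks=["p1", "p2", "p3"],
            normalized=True,
        )

    def test_arithmetic(self):
        ranked = acc.rank_by_fold_change(self._matrix(), "A", "B")
        assert ranked.log2_fold_change["p1"] == pytest.approx(np.log2(41 / 11))

    def test_equal_means_zero(self):
        ranked = acc.rank_by_fold_change(self._matrix(), "A", "B")
        assert ranked.log2_fold_change["p2"] == 0.0

    def test_swap_negates_and_reverses(self):
        ab = acc.rank_by_fold_change(self._matrix(), "A", "B")
        ba = acc.rank_by_fold_change(self._matrix(), "B", "A")
        for p in ["p1", "p2", "p3"]:
            assert ba.log2_fold_change[p] == pytest.approx(-ab.log2_fold_change[p])
        assert ba.peak_ids == list(reversed(ab.peak_ids))

    def test_unknown_group_is_error(self):
        with pytest.raises(ValueError, match="unknown group"):
            acc.rank_by_fold_change(self._matrix(), "A", "Z")

    def test_requires_normalized(self):
        m = make_matrix([[1, 2]], ["A_1", "B_1"], normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            acc.rank_by_fold_change(m, "A", "B")

    def test_ties_broken_lexicographically(self):
        m = make_matrix(
            [[10, 10], [10, 10]], ["A_1", "B_1"], peaks=["z", "a"], normalized=True
        )
        ranked = acc.rank_by_fold_change(m, "A", "B")
        assert ranked.peak_ids == ["a", "z"]


class TestSpecificSites:
    def _ranked(self):
        m = make_matrix(
            [[40, 10], [160, 10], [10, 40], [10, 10]],
            ["A_1", "B_1"],
            peaks=["p4x", "p16x", "pdown", "pflat"],
            normalized=True,
        )
        return acc.rank_by_fold_change(m, "A", "B", pseudocount=0)

    def test_inclusive_threshold(self):
        ranked = self._ranked()
        set_a, set_b = acc.specific_sites(ranked, fold=4.0)
        assert "p4x" in set_a.peak_ids  # log2FC exactly 2.0
        assert "pdown" in set_b.peak_ids
        assert "pflat" not in set_a.peak_ids | set_b.peak_ids

    def test_disjoint_and_bounded(self):
        set_a, set_b = acc.specific_sites(self._ranked(), fold=2.0)
        assert not (set_a.peak_ids & set_b.peak_ids)
        assert len(set_a.peak_ids | set_b.peak_ids) <= 4

    def test_monotone_in_fold(self):
        ranked = self._ranked()
        prev_a, prev_b = acc.specific_sites(ranked, fold=2.0)
        for fold in (3.0, 4.0, 8.0, 32.0):
            cur_a, cur_b = acc.specific_sites(ranked, fold=fold)
            assert cur_a.peak_ids <= prev_a.peak_ids
            assert cur_b.peak_ids <= prev_b.peak_ids
            prev_a, prev_b = cur_a, cur_b

    def test_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            acc.specific_sites(self._ranked(), fold=1.0)


class TestDensityMatrix:
    def _ranked(self, peaks):
        m = make_matrix(
            [[10, 1]] * len(peaks), ["A_1", "B_1"], peaks=peaks, normalized=True
        )
        return acc.rank_by_fold_change(m, "A", "B")

    def test_constant_profile(self):
        profiles = {"p0": np.full(2000, 3)}
        dm = acc.density_matrix(profiles, self._ranked(["p0"]))
        assert dm.shape == (1, 100)
        assert (dm.values == 60).all()

    def test_row_sums_conserved(self, rng):
        peaks = [f"p{i}" for i in range(5)]
        profiles = {p: rng.poisson(2, 2000) for p in peaks}
        dm = acc.density_matrix(profiles, self._ranked(peaks))
        for p in peaks:
            assert dm.loc[p].sum() == profiles[p].sum()

    def test_missing_profile_named(self):
        with pytest.raises(ValueError, match="p0"):
            acc.density_matrix({}, self._ranked(["p0"]))


class TestAverageProfile:
    def test_single_site_identity(self):
        prof = np.arange(2000)
        out = acc.average_profile({"p": prof}, ["p"])
        np.testing.assert_allclose(out, prof)

    def test_two_sites_elementwise_mean(self):
        a, b = np.zeros(2000), np.full(2000, 4.0)
        out = acc.average_profile({"a": a, "b": b}, ["a", "b"])
        np.testing.assert_allclose(out, 2.0)

    def test_linearity_of_means(self, rng):
        profiles = {f"p{i}": rng.poisson(3, 2000) for i in range(7)}
        out = acc.average_profile(profiles, list(profiles))
        per_site = np.mean([p.mean() for p in profiles.values()])
        assert out.mean() == pytest.approx(per_site, abs=1e-9)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            acc.average_profile({}, [])
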