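"""Contact-matrix core: binning, masking, ICE balancing, expected/O-E maps."""

import numpy as np
import pytest

import kelpfold as kf
from kelpfold.matrix import correlation_map

from conftest import uniform_matrix


class TestGenomeSpec:
    @pytest.mark.parametrize("bin_size", [2_000, 5_000, 10_000, 20_000, 50_000, 100_000, 500_000])
    def test_standard_bin_sizes_accepted(self, bin_size):
        g = kf.GenomeSpec([("c1", 2_000_000), ("c2", 1_500_000)], bin_size)
        assert g.n_bins == -(-2_000_000 // bin_size) + -(-1_500_000 // bin_size)

    def test_bins_tile_chromosomes_exactly(self):
        g = kf.GenomeSpec([("c1", 25_000)], 10_000)
        bins = g.bins()
        assert list(bins["start"]) == [0, 10_000, 20_000]
        assert list(bins["end"]) == [10_000, 20_000, 25_000]  # last bin short
        assert list(bins["index"]) == [0, 1, 2]

    def test_rejects_bin_size_larger_than_smallest_chromosome(self):
        with pytest.raises(ValueError):
            kf.GenomeSpec([("c1", 100_000), ("c2", 5_000)], 10_000)

    def test_bin_index_bounds(self):
        g = kf.GenomeSpec([("c1", 100_000)], 10_000)
        assert g.bin_index("c1", 0) == 0
        assert g.bin_index("c1", 99_999) == 9
        with pytest.raises(ValueError):
            g.bin_index("c1", 100_000)
        with pytest.raises(KeyError):
            g.bin_index("cX", 0)


class TestBinPairs:
    def test_empty_stream_gives_zero_matrix(self, toy_genome):
        m = kf.bin_pairs([], toy_genome)
        assert m.total_count == 0
        assert not m.counts.any()

    def test_toy_pair_assignment(self):
        g = kf.GenomeSpec([("c1", 10_000), ("c2", 10_000)], 2_000)
        pairs = [("c1", 1500, "c1", 3500), ("c1", 3500, "c1", 1500), ("c1", 100, "c2", 100)]
        m = kf.bin_pairs(pairs, g)
        c2_bin0 = g.chrom_offset("c2")
        assert m.counts[0, 1] == 2  # both orderings hit the same unordered cell
        assert m.counts[1, 0] == 2
        assert m.counts[0, c2_bin0] == 1
        assert m.total_count == 3

    def test_symmetry_and_count_conservation(self, toy_genome):
        rng = np.random.default_rng(0)
        pairs = [
            ("c1", int(rng.integers(1, 100_000)), "c2", int(rng.integers(1, 100_000)))
            for _ in range(500)
        ]
        m = kf.bin_pairs(pairs, toy_genome)
        assert np.array_equal(m.counts, m.counts.T)
        assert m.total_count == 500

    def test_invalid_records_dropped_or_raised(self, toy_genome):
        bad = [("c1", 1, "cX", 1), ("c1", 200_000, "c2", 1), ("c1", 5, "c2", 5)]
        m = kf.bin_pairs(bad, toy_genome)
        assert m.total_count == 1
        with pytest.raises(ValueError):
            kf.bin_pairs(bad, toy_genome, strict=True)


class TestMasking:
    def test_uniform_matrix_unmasked(self, uniform_map):
        m = kf.mask_low_coverage(uniform_map, 0.1)
        assert not m.masked.any()

    def test_zero_bin_masked(self, toy_genome):
        m = uniform_matrix(toy_genome)
        m.counts[3, :] = 0
        m.counts[:, 3] = 0
        masked = kf.mask_low_coverage(m).masked
        assert masked[3] and masked.sum() == 1

    def test_low_coverage_bin_masked(self):
        g = kf.GenomeSpec([("c1", 100_000)], 10_000)
        counts = np.full((10, 10), 10.0)
        counts[7, :] *= 0.05  # 5% of median marginal
        counts[:, 7] = counts[7, :]
        masked = kf.mask_low_coverage(kf.ContactMatrix(g, (counts + counts.T) / 2), 0.1).masked
        assert masked[7] and masked.sum() == 1

    def test_all_masked_raises(self, toy_genome):
        n = toy_genome.n_bins
        m = kf.ContactMatrix(toy_genome, np.zeros((n, n)))
        with pytest.raises(ValueError, match="degenerate"):
            kf.mask_low_coverage(m)


class TestIceBalance:
    def test_equal_marginals_give_equal_weights(self, uniform_map):
        m = kf.ice_balance(uniform_map)
        w = m.weights
        assert np.allclose(w, w[0])

    def test_2x2_closed_form(self):
        g = kf.GenomeSpec([("c1", 4_000)], 2_000)
        m = kf.ice_balance(kf.ContactMatrix(g, np.array([[0.0, 4.0], [4.0, 0.0]])))
        bal = m.balanced()
        # unit-target marginals: the off-diagonal balanced value is exactly 1
        assert bal[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert bal[0, 1] == pytest.approx(bal[1, 0])

    def test_marginal_equality_within_tol(self):
        rng = np.random.default_rng(1)
        a = rng.random((20, 20)) + 0.5
        counts = a + a.T
        g = kf.GenomeSpec([("c1", 200_000)], 10_000)
        m = kf.ice_balance(kf.ContactMatrix(g, counts), tol=1e-7)
        marg = np.nansum(m.balanced(), axis=0)
        assert np.std(marg) / np.mean(marg) < 1e-5

    def test_scale_invariance_of_weight_ratios_and_oe(self):
        rng = np.random.default_rng(2)
        a = rng.random((15, 15)) + 0.5
        counts = a + a.T
        g = kf.GenomeSpec([("c1", 150_000)], 10_000)
        m1 = kf.ice_balance(kf.ContactMatrix(g, counts))
        m2 = kf.ice_balance(kf.ContactMatrix(g, 2 * counts))
        assert np.allclose(m1.weights / m1.weights[0], m2.weights / m2.weights[0], atol=1e-6)
        oe1 = kf.observed_over_expected(m1)
        oe2 = kf.observed_over_expected(m2)
        assert np.allclose(oe1, oe2, atol=1e-6, equal_nan=True)

    def test_counts_untouched_by_balancing(self, uniform_map):
        before = uniform_map.counts.copy()
        kf.ice_balance(uniform_map)
        assert np.array_equal(uniform_map.counts, before)

    def test_nonconvergence_raises(self):
        rng = np.random.default_rng(4)
        a = rng.random((10, 10)) + 0.1
        g = kf.GenomeSpec([("c1", 100_000)], 10_000)
        with pytest.raises(RuntimeError, match="residual"):
            kf.ice_balance(kf.ContactMatrix(g, a + a.T), tol=1e-300, max_iter=2)


class TestExpectedAndOE:
    def test_constant_matrix_constant_expectation(self, uniform_map):
        e = kf.expected_profile(uniform_map)
        for chrom in ("c1", "c2"):
            assert np.allclose(e.cis[chrom], 4.0)
        assert e.trans[("c1", "c2")] == pytest.approx(4.0)

    def test_hand_averaged_diagonals(self):
        g = kf.GenomeSpec([("c1", 40_000)], 10_000)
        counts = np.zeros((4, 4))
        for d, v in enumerate([10.0, 4.0, 2.0, 1.0]):
            counts += np.diag(np.full(4 - d, v), k=d)
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = kf.ContactMatrix(g, counts, weights=np.ones(4))
        e = kf.expected_profile(m)
        assert np.allclose(e.cis["c1"], [10, 4, 2, 1])

    def test_masked_bin_excluded_from_profile(self):
        g = kf.GenomeSpec([("c1", 40_000)], 10_000)
        counts = np.full((4, 4), 2.0)
        counts[0, 1] = counts[1, 0] = 100.0  # large value on a soon-masked bin
        m = kf.ContactMatrix(g, counts, weights=np.ones(4), masked=np.array([True, False, False, False]))
        e = kf.expected_profile(m)
        assert np.allclose(e.cis["c1"][:3], 2.0)

    def test_oe_identity_is_ones(self, uniform_map):
        oe = kf.observed_over_expected(uniform_map)
        v = uniform_map.valid
        assert np.allclose(oe[np.ix_(v, v)], 1.0)

    def test_oe_hand_division(self):
        g = kf.GenomeSpec([("c1", 40_000)], 10_000)
        counts = np.zeros((4, 4))
        for d, v in enumerate([10.0, 4.0, 2.0, 1.0]):
            counts += np.diag(np.full(4 - d, v), k=d)
        counts = np.triu(counts) + np.triu(counts, 1).T
        counts[0, 1] = counts[1, 0] = 8.0  # one perturbed cell; diag-1 mean = (8+4+4)/3
        m = kf.ContactMatrix(g, counts, weights=np.ones(4))
        oe = kf.observed_over_expected(m)
        exp1 = (8 + 4 + 4) / 3
        assert oe[0, 1] == pytest.approx(8 / exp1)
        assert oe[1, 2] == pytest.approx(4 / exp1)
        assert oe[0, 0] == pytest.approx(1.0)

    def test_undefined_cells_are_nan_not_zero(self):
        g = kf.GenomeSpec([("c1", 40_000)], 10_000)
        counts = np.full((4, 4), 3.0)
        masked = np.array([False, True, False, False])
        m = kf.ContactMatrix(g, counts, weights=np.ones(4), masked=masked)
        oe = kf.observed_over_expected(m)
        assert np.isnan(oe[1, :]).all() and np.isnan(oe[:, 1]).all()


class TestCorrelationMap:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        a = rng.random((8, 8))
        corr = correlation_map(a + a.T)
        assert np.allclose(np.diagonal(corr), 1.0)

    def test_identical_rows_correlate_fully(self):
        row = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a = np.tile(row, (5, 1))
        corr = correlation_map(a)
        assert corr[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 20)
        a = rng.random((n, n))
        a = a + a.T
        if seed == 2:  # exercise the general-NaN path too
            a[0, 3] = np.nan
            a[3, 0] = np.nan
        corr = correlation_map(a)
        for i in range(n):
            for j in range(n):
                ok = np.isfinite(a[i]) & np.isfinite(a[j])
                expected = np.corrcoef(a[i, ok], a[j, ok])[0, 1]
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rows_masked(self):
        corr = correlation_map(np.ones((4, 4)))
        assert np.isnan(corr).all()  # constant rows have no defined correlation
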