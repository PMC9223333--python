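"""Sharing counts, distance binning and the direct profile engines."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ascdecay as ad
from ascdecay.io import DataError
from ascdecay.sharing import DistanceBins

from conftest import make_dataset

GENO = st.sampled_from([0, 1, 2, 9])


class TestSharingCount:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [(2, 2, 2), (0, 0, 2), (0, 2, 0), (2, 0, 0), (1, 1, 1), (1, 0, 1), (1, 2, 1), (9, 2, None), (0, 9, None)],
    )
    def test_examples(self, ga, gb, expected):
        assert ad.sharing_count(ga, gb) == expected

    @given(GENO, GENO)
    @settings(deadline=None)
    def test_symmetric_and_allele_label_invariant(self, ga, gb):
        assert ad.sharing_count(ga, gb) == ad.sharing_count(gb, ga)
        if ga != 9 and gb != 9:
            # swapping ref/alt labels maps g -> 2 - g and leaves IBS unchanged
            assert ad.sharing_count(ga, gb) == ad.sharing_count(2 - ga, 2 - gb)

    def test_vectorized_matches_scalar(self):
        codes = [0, 1, 2, 9]
        ga, gb = zip(*itertools.product(codes, codes))
        vec = ad.sharing_values(np.array(ga), np.array(gb))
        for a, b, v in zip(ga, gb, vec):
            expected = ad.sharing_count(a, b)
            assert (expected is None and np.isnan(v)) or expected == v


class TestPairSharing:
    def test_pair_count_is_m_choose_2(self):
        ds = make_dataset(np.ones((3, 4), dtype=np.int8), [0.001, 0.002, 0.003])
        psm = ad.build_pair_sharing(ds, ad.within_pairs(ds.individual_ids))
        assert psm.n_pairs == 6

    def test_hand_built_toy(self):
        #        ind0 ind1 ind2
        ds = make_dataset([[0, 2, 1], [2, 2, 9], [1, 0, 0]], [0.001, 0.002, 0.003])
        psm = ad.build_pair_sharing(ds, [("ind0", "ind1"), ("ind0", "ind2"), ("ind1", "ind2")])
        expected = np.array([[0, 1, 1], [2, np.nan, np.nan], [1, 1, 2]])
        np.testing.assert_array_equal(psm.sharing, expected)

    def test_allele_swap_leaves_sharing_unchanged(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
        ds = make_dataset(g, np.sort(rng.random(10)) / 100)
        flipped = make_dataset((2 - g).astype(np.int8), ds.genetic_pos)
        pairs = ad.within_pairs(ds.individual_ids)
        np.testing.assert_array_equal(
            ad.build_pair_sharing(ds, pairs).sharing,
            ad.build_pair_sharing(flipped, pairs).sharing,
        )

    def test_unknown_id_errors(self):
        ds = make_dataset([[0, 2]], [0.001])
        with pytest.raises(DataError, match="nope"):
            ad.build_pair_sharing(ds, [("ind0", "nope")])


class TestBinning:
    def test_bin_assignment_and_exclusions(self):
        bins = DistanceBins(0.1, 30.0, 0.1)
        # 0.07 cM below min -> excluded; 0.15 -> first bin; 30.0 -> excluded
        idx = bins.index_of(np.array([0.07, 0.15, 0.1, 29.95, 30.0]))
        assert list(idx) == [-1, 0, 0, 298, -1]
        assert bins.n_bins == 299
        assert bins.mid_cM[0] == pytest.approx(0.15)

    def test_snp_pairs_cross_chromosome_excluded(self):
        chroms = ["1", "1", "2"]
        pos = np.array([0.0, 0.0015, 0.0016])
        mapping = ad.bin_snp_pairs(np.array(chroms, dtype=object), pos, DistanceBins(0.1, 30.0, 0.1))
        all_pairs = [p for pairs in mapping.values() for p in pairs]
        assert (0, 1) in all_pairs  # 0.15 cM apart, same chromosome
        assert not any(2 in p for p in all_pairs)


def brute_force_profile(psm, bins):
    """Independent oracle: double loop over SNP pairs, scipy Pearson r."""
    sums = np.zeros(bins.n_bins)
    counts = np.zeros(bins.n_bins)
    pos = psm.genetic_pos * 100
    for i in range(psm.n_snps):
        for j in range(i + 1, psm.n_snps):
            if psm.chromosomes[i] != psm.chromosomes[j]:
                continue
            b = bins.index_of(np.array([pos[j] - pos[i]]))[0]
            if b < 0:
                continue
            x = psm.sharing[i].astype(np.float64)
            y = psm.sharing[j].astype(np.float64)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 2 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            sums[b] += stats.pearsonr(x[ok], y[ok]).statistic
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


class TestNaiveProfiles:
    def test_identical_sharing_vectors_give_r_one(self):
        g = np.array([[0, 1, 2, 0, 2], [0, 1, 2, 0, 2]], dtype=np.int8)
        ds = make_dataset(g, [0.001, 0.0025])
        psm = ad.build_pair_sharing(ds, ad.within_pairs(ds.individual_ids))
        prof = ad.within_profile_naive(psm, DistanceBins(0.1, 1.0, 0.1))
        assert prof.value[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("missing_rate", [0.0, 0.3])
    def test_matches_brute_force_oracle(self, missing_rate):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, size=(24, 6)).astype(np.int8)
        if missing_rate:
            g[rng.random(g.shape) < missing_rate] = 9
        pos = np.sort(rng.random(24)) * 0.02
        chroms = ["1"] * 14 + ["2"] * 10
        ds = make_dataset(g, pos, chroms=chroms)
        psm = ad.build_pair_sharing(ds, ad.within_pairs(ds.individual_ids))
        bins = DistanceBins(0.1, 2.0, 0.1)
        prof = ad.within_profile_naive(psm, bins)
        expect, counts = brute_force_profile(psm, bins)
        m = np.isfinite(expect)
        np.testing.assert_array_equal(m, np.isfinite(prof.value))
        np.testing.assert_allclose(prof.value[m], expect[m], atol=1e-12)
        np.testing.assert_array_equal(prof.pooled()[1], counts)

    def test_individual_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
        pos = np.sort(rng.random(20)) * 0.02
        ds = make_dataset(g, pos)
        perm = rng.permutation(6)
        ds2 = make_dataset(g[:, perm], pos)
        bins = DistanceBins(0.1, 2.0, 0.1)
        p1 = ad.within_profile_naive(ad.build_pair_sharing(ds, ad.within_pairs(ds.individual_ids)), bins)
        p2 = ad.within_profile_naive(ad.build_pair_sharing(ds2, ad.within_pairs(ds2.individual_ids)), bins)
        np.testing.assert_allclose(p1.value, p2.value, atol=1e-12)

    def test_correlation_values_bounded(self, tiny_founder):
        ds = tiny_founder.subset_snps(np.arange(0, 2000))
        psm = ad.build_pair_sharing(ds, ad.within_pairs(ds.members_of("A")))
        prof = ad.within_profile_naive(psm, DistanceBins(0.1, 2.0, 0.1))
        v = prof.value
        assert np.nanmax(np.abs(v)) <= 1.0

    def test_cross_profile_uses_target_by_outgroup_pairs(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
        ds = make_dataset(g, np.sort(rng.random(20)) * 0.02, populations=["A"] * 5 + ["B"])
        prof = ad.cross_profile_naive(ds, "A", ["ind5"], DistanceBins(0.1, 2.0, 0.1))
        psm = ad.build_pair_sharing(ds, ad.cross_pairs(ds.members_of("A"), ["ind5"]))
        assert psm.n_pairs == 5
        np.testing.assert_allclose(prof.value, ad.within_profile_naive(psm, prof.bins).value, atol=1e-12)

    def test_outgroup_overlapping_target_rejected(self):
        ds = make_dataset(np.ones((2, 3), dtype=np.int8), [0.001, 0.002])
        with pytest.raises(DataError, match="overlap"):
            ad.cross_profile_naive(ds, "A", ["ind0"], DistanceBins(0.1, 1.0, 0.1))


class TestCorrectedProfile:
    def _profiles(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        ds = make_dataset(g, np.sort(rng.random(30)) * 0.02, populations=["A"] * 6 + ["B"] * 2)
        bins = DistanceBins(0.1, 2.0, 0.1)
        zw = ad.within_profile_naive(ad.build_pair_sharing(ds, ad.within_pairs(ds.members_of("A"))), bins)
        zc = ad.cross_profile_naive(ds, "A", ds.members_of("B"), bins)
        return zw, zc

    def test_subtraction_per_bin(self):
        zw, zc = self._profiles()
        z = ad.corrected_profile(zw, zc)
        m = np.isfinite(zw.value) & np.isfinite(zc.value)
        np.testing.assert_allclose(z.value[m], zw.value[m] - zc.value[m], atol=1e-12)
        # absent in either input -> absent in output
        assert not np.isfinite(z.value[~m]).any()

    def test_bin_mismatch_errors(self):
        zw, zc = self._profiles()
        rng = np.random.default_rng(7)
        other = ad.within_profile_naive(
            ad.build_pair_sharing(
                make_dataset(rng.integers(0, 3, size=(5, 4)), np.arange(5) * 0.004),
                ad.within_pairs([f"ind{k}" for k in range(4)]),
            ),
            DistanceBins(0.1, 1.0, 0.1),
        )
        with pytest.raises(DataError, match="bins"):
            ad.corrected_profile(zw, other)


class TestHeterozygosityAndWeighted:
    @pytest.mark.parametrize("p,he", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.2, 0.32)])
    def test_expected_heterozygosity(self, p, he):
        assert ad.expected_heterozygosity(p) == pytest.approx(he)

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ad.expected_heterozygosity(1.2)

    def test_reference_allele_frequency_ignores_missing(self):
        g = np.array([[0, 2, 9], [2, 2, 2]])
        np.testing.assert_allclose(ad.reference_allele_frequency(g), [0.5, 1.0])

    def test_weighted_cov_matches_hand_computation(self):
        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, size=(12, 6)).astype(np.int8)
        ds = make_dataset(g, np.sort(rng.random(12)) * 0.02)
        psm = ad.build_pair_sharing(ds, ad.within_pairs(ds.individual_ids))
        he = np.full(12, 0.5)
        bins = DistanceBins(0.1, 2.0, 0.1)
        prof = ad.weighted_cov_profile(psm, he, bins)
        # hand: per SNP pair cov of sharing FRACTIONS / (He_i He_j), bin mean
        pos = psm.genetic_pos * 100
        sums = np.zeros(bins.n_bins)
        counts = np.zeros(bins.n_bins)
        for i in range(12):
            for j in range(i + 1, 12):
                b = bins.index_of(np.array([pos[j] - pos[i]]))[0]
                if b < 0:
                    continue
                c = np.cov(psm.sharing[i] / 2, psm.sharing[j] / 2, ddof=1)[0, 1]
                sums[b] += c / 0.25
                counts[b] += 1
        m = counts > 0
        np.testing.assert_allclose(prof.value[m], sums[m] / counts[m], atol=1e-12)

    def test_zero_he_rejected(self):
        ds = make_dataset(np.ones((3, 4), dtype=np.int8), [0.001, 0.002, 0.003])
        psm = ad.build_pair_sharing(ds, ad.within_pairs(ds.individual_ids))
        with pytest.raises(DataError, match="positive"):
            ad.weighted_cov_profile(psm, np.array([0.5, 0.0, 0.5]), DistanceBins(0.1, 1.0, 0.1))
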