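"""Haplotyper: segment matching, complements, library growth, imputation."""

import numpy as np
import pytest

from herd import ldsim
from herd.haplotyper import (HaplotypeImputer, complement, is_match,
                             segment_boundaries)

from _oracles import parsimony_phasing_min


def matrix(rows, missing=None):
    codes = np.asarray(rows, dtype=np.int8)
    miss = np.zeros_like(codes, dtype=bool) if missing is None else np.asarray(missing, bool)
    codes = np.where(miss, 1, codes).astype(np.int8)
    return ldsim.GenotypeMatrix(codes, miss)


class TestSegments:
    @pytest.mark.parametrize("n,size,expected", [
        (250, 100, [(0, 100), (100, 200), (200, 250)]),
        (100, 100, [(0, 100)]),
        (57, 100, [(0, 57)]),  # a chromosome shorter than one segment
    ])
    def test_boundaries_cover_without_overlap(self, n, size, expected):
        assert segment_boundaries(n, size) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            segment_boundaries(0, 100)
        with pytest.raises(ValueError):
            segment_boundaries(100, 0)


class TestMatching:
    def test_heterozygotes_and_unknowns_never_conflict(self):
        assert is_match([0, 1, 2], [0, 1, 1])

    def test_homozygous_conflict_breaks_match(self):
        assert not is_match([0, 1, 2], [2, 0, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            is_match([0, 1], [0, 1, 2])

    def test_scan_returns_first_non_conflicting_entry(self):
        from herd import _kernels
        lib = np.array([[2, 1, 2], [2, 0, 0], [0, 1, 1]], dtype=np.int8)
        g = np.array([0, 1, 2], dtype=np.int8)
        assert _kernels.first_match(lib, 3, g, 0) == 2


class TestComplement:
    def test_observed_heterozygote_forces_opposite_allele(self):
        c = complement([0, 1, 2], [0, 0, 2])
        assert np.array_equal(c, [0, 2, 2])

    def test_homozygous_genotype_forces_equality(self):
        assert np.array_equal(complement([0, 2], [0, 2]), [0, 2])

    def test_missing_locus_stays_unknown(self):
        c = complement([0, 1, 2], [0, 2, 2], missing=[False, True, False])
        assert c[1] == 1

    def test_non_matching_pair_rejected(self):
        with pytest.raises(ValueError):
            complement([0, 1, 2], [2, 1, 2])

    def test_reconstruction_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h1 = rng.integers(0, 2, 12).astype(np.int8) * 2
            h2 = rng.integers(0, 2, 12).astype(np.int8) * 2
            g = ((h1 + h2) // 2).astype(np.int8)
            c = complement(g, h1)
            known = c != 1
            assert np.array_equal(((h1 + c) // 2)[known], g[known])


class TestLibraryGrowth:
    def test_identical_homozygous_genotypes_share_one_entry_counted_four_times(self):
        gm = matrix([[0, 0, 2], [0, 0, 2]])
        imp = HaplotypeImputer(segment_size=3, n_iterations=2)
        imp.fit(gm)
        seg = imp.library_.segments[0]
        assert seg.n_entries == 1
        assert np.array_equal(seg.lib[0], [0, 0, 2])
        assert seg.counts[0] == 4

    def test_genotype_entry_split_by_homozygous_match(self):
        # first animal het at one locus is stored as a genotype-entry; a
        # homozygous match splits it, and the owner's complement completes
        # the second haplotype
        gm = matrix([[0, 1, 0, 2], [0, 0, 0, 2]])
        imp = HaplotypeImputer(segment_size=4, n_iterations=2)
        imp.fit(gm)
        seg = imp.library_.segments[0]
        entries = {seg.lib[i].tobytes() for i in range(seg.n_entries)}
        assert np.array([0, 0, 0, 2], dtype=np.int8).tobytes() in entries
        assert np.array([0, 2, 0, 2], dtype=np.int8).tobytes() in entries
        out = imp.imputed_
        assert np.all(out.hap_pat[0] != 1) and np.all(out.hap_mat[0] != 1)

    def test_count_conservation(self, small_run):
        _, imp = small_run
        for seg in imp.library_.segments:
            both = np.count_nonzero((seg.hp >= 0) & (seg.hm >= 0))
            one = np.count_nonzero((seg.hp >= 0) ^ (seg.hm >= 0))
            assert seg.counts[: seg.n_entries].sum() == 2 * both + one

    def test_frequency_sort_is_non_increasing(self, small_run):
        _, imp = small_run
        for seg in imp.library_.segments:
            c = seg.counts[: seg.n_entries]
            assert np.all(np.diff(c) <= 0)


class TestRun:
    def test_clean_input_passes_through(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, (8, 40)).astype(np.int8)
        gm = matrix(codes)
        imp = HaplotypeImputer(segment_size=20, n_iterations=6)
        imp.fit(gm)
        out = imp.imputed_
        assert np.array_equal(np.rint(out.dosage).astype(np.int8), codes)
        assert np.all(out.provenance == 0)
        assert np.allclose(out.call_rate, 1.0)

    def test_nuclear_family_low_density_child_recovered(self):
        # homozygous parents determine the child completely; the child is
        # genotyped at every 10th marker only
        rng = np.random.default_rng(2)
        L = 100
        sire = (rng.integers(0, 2, L) * 2).astype(np.int8)
        dam = (rng.integers(0, 2, L) * 2).astype(np.int8)
        child = ((sire + dam) // 2).astype(np.int8)
        miss = np.zeros((3, L), dtype=bool)
        miss[2, np.arange(L) % 10 != 0] = True
        gm = matrix([sire, dam, child], missing=miss)
        ped = ldsim.Pedigree(
            ids=np.array(["s", "d", "c"], dtype=object),
            sire=np.array([-1, -1, 0], np.int32), dam=np.array([-1, -1, 1], np.int32),
            cohort=np.array([1, 3, 2], np.int8),
            density=np.array([2, 2, 1], np.int8))
        imp = HaplotypeImputer(pedigree=ped, segment_size=50, n_iterations=6)
        imp.fit(gm)
        out = imp.imputed_
        masked = miss[2]
        called = out.provenance[2] == 1
        assert (called & masked).sum() >= 0.9 * masked.sum()
        got = np.rint(out.dosage[2, masked & called]).astype(np.int8)
        assert np.array_equal(got, child[masked & called])

    def test_phasing_matches_exhaustive_parsimony_oracle(self):
        rng = np.random.default_rng(3)
        founders = (rng.integers(0, 2, (3, 8)) * 2).astype(np.int8)
        pairs = rng.integers(0, 3, (12, 2))
        G = ((founders[pairs[:, 0]] + founders[pairs[:, 1]]) // 2).astype(np.int8)
        imp = HaplotypeImputer(segment_size=8, n_iterations=6)
        imp.fit(matrix(G.copy()))
        out = imp.imputed_
        assert np.all(out.hap_pat != 1) and np.all(out.hap_mat != 1)
        assert np.array_equal(((out.hap_pat + out.hap_mat) // 2).astype(np.int8), G)
        distinct = {h.tobytes() for h in np.vstack([out.hap_pat, out.hap_mat])}
        assert len(distinct) == parsimony_phasing_min(G)


class TestInvariants:
    def test_no_assigned_haplotype_conflicts_with_observed_homozygotes(self, small_run):
        sc, imp = small_run
        out = imp.imputed_
        G, M = imp._G, imp._M
        for hap in (out.hap_pat, out.hap_mat):
            bad = (~M) & (G != 1) & (hap != 1) & (G != hap)
            assert not bad.any()

    def test_unknown_allele_fraction_never_increases(self, small_run):
        _, imp = small_run
        f = [s["unknown_allele_fraction"] for s in imp.iteration_stats_]
        assert all(b <= a + 1e-12 for a, b in zip(f, f[1:]))

    def test_call_rate_threshold_controls_usable_ancestors(self, small_run):
        sc, imp = small_run
        out = imp.imputed_
        anc = ~sc.pedigree.genotyped()
        assert np.all(out.call_rate[out.usable] >= imp.call_rate_threshold)
        assert np.all(anc[out.usable])


class TestCallGenotypes:
    def test_fill_rules(self):
        # one animal, two loci missing: one half-known, one unknown
        gm = matrix([[2, 1, 1], [2, 2, 0], [2, 2, 0]],
                    missing=[[False, True, True], [False, False, False],
                             [False, False, False]])
        imp = HaplotypeImputer(segment_size=3, n_iterations=2)
        imp.fit(gm)
        out = imp.imputed_
        freq = imp.allele_freq_
        prov = out.provenance[0]
        for locus in (1, 2):
            if prov[locus] == 2:   # half filled: known allele + frequency
                known = (out.hap_pat[0, locus] if out.hap_pat[0, locus] != 1
                         else out.hap_mat[0, locus]) / 2
                assert out.dosage[0, locus] == pytest.approx(known + freq[locus])
            elif prov[locus] == 3:  # frequency filled
                assert out.dosage[0, locus] == pytest.approx(2 * freq[locus])
            else:
                assert prov[locus] == 1

    def test_call_rate_counts_half_filled_as_half(self, small_run):
        _, imp = small_run
        out = imp.imputed_
        p = out.provenance
        expect = (np.isin(p, (0, 1)) + 0.5 * (p == 2)).mean(axis=1)
        assert np.allclose(out.call_rate, expect)
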