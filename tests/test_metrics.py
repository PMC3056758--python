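"""Imputation-success metrics against simulation truth."""

import numpy as np
import pytest

from herd import metrics
from herd.haplotyper import ImputedGenotypes


def make_imputed(dosage, provenance, hap_pat=None, hap_mat=None):
    dosage = np.asarray(dosage, dtype=np.float32)
    provenance = np.asarray(provenance, dtype=np.int8)
    n, m = dosage.shape
    if hap_pat is None:
        hap_pat = np.full((n, m), 1, np.int8)
        hap_mat = np.full((n, m), 1, np.int8)
    p = (np.isin(provenance, (0, 1)) + 0.5 * (provenance == 2)).mean(axis=1)
    return ImputedGenotypes(dosage=dosage, provenance=provenance,
                            call_rate=p, hap_pat=np.asarray(hap_pat, np.int8),
                            hap_mat=np.asarray(hap_mat, np.int8),
                            oriented=np.zeros((n, 1), bool),
                            usable=np.zeros(n, bool))


def haps(pat, mat):
    return np.stack([np.asarray(pat, np.int8), np.asarray(mat, np.int8)], axis=0)[None]


class TestImputationReport:
    def test_perfect_imputation_scores_zero_errors(self):
        truth = np.array([[0, 1, 2, 2]], dtype=np.int8)
        th = haps([0, 2, 2, 2], [0, 0, 2, 2])
        imp = make_imputed(truth, [[0, 0, 1, 1]], [[0, 2, 2, 2]], [[0, 0, 2, 2]])
        rep = metrics.imputation_report(imp, truth, th, old_mask=np.array([False]),
                                        missing_before=np.array([[False, False, True, True]]),
                                        scored=np.array([True]))
        row = rep.loc["young"]
        assert row.pct_incorrect_genotypes == 0
        assert row.genotype_error_rate == 0
        assert row.pct_missing_before == 50.0
        assert row.pct_missing_after == 0.0
        assert row.mean_rel_snp == pytest.approx(1.0)

    def test_hand_counted_example(self):
        # 8 loci, 2 originally missing; one imputed correctly, one called as
        # the opposite homozygote
        truth = np.array([[0, 0, 1, 1, 2, 2, 0, 2]], dtype=np.int8)
        est = np.array([[0, 0, 1, 1, 2, 2, 0, 0]], dtype=np.float32)
        prov = np.array([[0, 0, 0, 0, 0, 0, 1, 1]], dtype=np.int8)
        before = np.zeros((1, 8), bool)
        before[0, 6:] = True
        imp = make_imputed(est, prov)
        rep = metrics.imputation_report(imp, truth, haps([1]*8, [1]*8),
                                        old_mask=np.array([False]),
                                        missing_before=before,
                                        scored=np.array([True]))
        row = rep.loc["young"]
        assert row.pct_missing_before == 25.0
        assert row.pct_incorrect_genotypes == pytest.approx(12.5)
        # half-error rate over the 2 imputed loci: one opposite homozygote
        assert row.genotype_error_rate == pytest.approx(50.0)

    def test_imputed_het_against_hom_truth_is_half_an_error(self):
        truth = np.array([[2, 2]], dtype=np.int8)
        est = np.array([[1, 2]], dtype=np.float32)
        prov = np.array([[1, 1]], dtype=np.int8)
        rep = metrics.imputation_report(make_imputed(est, prov), truth,
                                        haps([1, 1], [1, 1]),
                                        old_mask=np.array([False]),
                                        missing_before=np.ones((1, 2), bool),
                                        scored=np.array([True]))
        assert rep.loc["young"].genotype_error_rate == pytest.approx(25.0)

    def test_group_decomposition(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, (10, 30)).astype(np.int8)
        est = truth.copy().astype(np.float32)
        flip = rng.random((10, 30)) < 0.2
        est[flip] = (est[flip] + 1) % 3
        prov = np.where(rng.random((10, 30)) < 0.5, 0, 1).astype(np.int8)
        old = np.arange(10) < 4
        rep = metrics.imputation_report(make_imputed(est, prov), truth,
                                        np.ones((10, 2, 30), np.int8),
                                        old_mask=old,
                                        missing_before=np.zeros((10, 30), bool),
                                        scored=np.ones(10, bool))
        w_old, w_young = 4 / 10, 6 / 10
        combined = (w_old * rep.loc["old"].pct_incorrect_genotypes
                    + w_young * rep.loc["young"].pct_incorrect_genotypes)
        assert rep.loc["all"].pct_incorrect_genotypes == pytest.approx(combined)

    def test_invariant_to_animal_ordering(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, (8, 20)).astype(np.int8)
        est = truth.astype(np.float32).copy()
        est[rng.random((8, 20)) < 0.1] = 0
        prov = rng.integers(0, 2, (8, 20)).astype(np.int8)
        th = rng.integers(0, 2, (8, 2, 20)).astype(np.int8) * 2
        old = rng.random(8) < 0.5
        perm = rng.permutation(8)
        a = metrics.imputation_report(make_imputed(est, prov), truth, th, old,
                                      np.zeros((8, 20), bool), np.ones(8, bool))
        b = metrics.imputation_report(make_imputed(est[perm], prov[perm]),
                                      truth[perm], th[perm], old[perm],
                                      np.zeros((8, 20), bool), np.ones(8, bool))
        assert np.allclose(a.loc["all"].drop("n_animals").astype(float),
                           b.loc["all"].drop("n_animals").astype(float))


class TestPhaseError:
    def test_exact_phasing_has_zero_error(self):
        th = haps([0, 2, 0, 2], [2, 0, 2, 0])[0]
        assert metrics.phase_error_rate(th[None, 0], th[None, 1], th[None]) == 0.0

    def test_one_flipped_pair_of_three_heterozygotes_is_fifty_percent(self):
        truth = haps([0, 2, 2], [2, 0, 0])[0]
        est_p = np.array([[0, 2, 0]], np.int8)
        est_m = np.array([[2, 0, 2]], np.int8)
        assert metrics.phase_error_rate(est_p, est_m, truth[None]) == pytest.approx(50.0)

    def test_homozygous_animal_contributes_no_pairs(self):
        truth = haps([2, 2, 2], [2, 2, 2])[0]
        assert metrics.phase_error_rate(truth[None, 0], truth[None, 1], truth[None]) == 0.0


class TestPaternalOrigin:
    def test_correct_labels_score_zero(self):
        truth = haps([0, 2, 0], [2, 0, 2])[0]
        assert metrics.paternal_origin_error_rate(truth[None, 0], truth[None, 1],
                                                  truth[None]) == 0.0

    def test_globally_swapped_labels_score_one_hundred(self):
        truth = haps([0, 2, 0], [2, 0, 2])[0]
        assert metrics.paternal_origin_error_rate(truth[None, 1], truth[None, 0],
                                                  truth[None]) == 100.0

    def test_scored_only_where_phase_determined(self):
        truth = haps([0, 2, 0], [2, 0, 2])[0]
        est_p = np.array([[0, 1, 2]], np.int8)   # locus 1 unknown, locus 2 swapped
        est_m = np.array([[2, 1, 0]], np.int8)
        assert metrics.paternal_origin_error_rate(est_p, est_m,
                                                  truth[None]) == pytest.approx(50.0)


class TestRelSnp:
    def test_exact_estimate_gives_one(self):
        t = np.array([[0, 1, 2, 1, 0]], float)
        assert metrics.rel_snp(t, t)[0] == pytest.approx(1.0)

    def test_constant_estimate_gives_zero(self):
        t = np.array([[0, 1, 2, 1, 0]], float)
        e = np.full_like(t, 0.6)
        assert metrics.rel_snp(e, t)[0] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 3, (5, 40)).astype(float)
        e = t + rng.normal(0, 0.3, t.shape)
        assert np.allclose(metrics.rel_snp(e, t), metrics.rel_snp(2 * e + 1, t))


class TestHaplotypeStats:
    def test_single_entry_library(self, small_run):
        _, imp = small_run
        stats = metrics.haplotype_stats(imp.library_)
        total = sum(int(s.counts[: s.n_entries].sum()) for s in imp.library_.segments)
        distinct = sum(s.n_entries for s in imp.library_.segments)
        assert stats.mean_observations_per_haplotype == pytest.approx(total / distinct)
        assert 0 < stats.most_frequent_share <= 1

    def test_trivial_two_animal_case(self):
        from herd.haplotyper import HaplotypeImputer
        from herd.ldsim import GenotypeMatrix
        codes = np.array([[0, 0, 2], [0, 0, 2]], np.int8)
        imp = HaplotypeImputer(segment_size=3, n_iterations=2)
        imp.fit(GenotypeMatrix(codes, np.zeros_like(codes, bool)))
        stats = metrics.haplotype_stats(imp.library_)
        assert stats.mean_haplotypes_per_segment == 1
        assert stats.most_frequent_share == 1.0
        assert stats.mean_observations_per_haplotype == 4


class TestLdCurve:
    def test_independent_markers_have_near_zero_r2(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, (400, 200)).astype(float)
        from herd.ldsim import MarkerMap
        m = MarkerMap(np.zeros(200, np.int32), np.sort(rng.random(200)),
                      np.full(200, 0.5), np.zeros(200, bool))
        curve = metrics.ld_r2_by_distance(dosage, m, bins=[0, 0.5, 1.0], seed=0)
        # E[r^2] under independence is ~1/(n-1)
        assert np.nanmax(curve["mean_r2"]) < 3.0 / 399
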