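"""Simulator: marker maps, LD founders, gene drop, QTL, artifacts, masking."""

import numpy as np
import pytest
from scipy import stats

from herd import ldsim


def cfg(**kw):
    defaults = dict(n_chromosomes=1, n_markers_total=100, n_qtl=0)
    defaults.update(kw)
    return ldsim.SimConfig(**defaults)


class TestMarkerMap:
    def test_positions_sorted_and_frequencies_open_interval(self):
        m = ldsim.make_marker_map(cfg(n_markers_total=10), rng=0)
        assert m.n_markers == 10
        assert np.all(np.diff(m.position) > 0)
        assert np.all((m.position >= 0) & (m.position < 1))
        assert np.all((m.freq > 0) & (m.freq < 1))

    def test_near_equal_allocation_across_chromosomes(self):
        m = ldsim.make_marker_map(cfg(n_chromosomes=30, n_markers_total=500_000), rng=0)
        starts, stops = m.chrom_bounds()
        counts = stops - starts
        assert counts.sum() == 500_000
        assert counts.max() - counts.min() <= 1
        assert np.isclose(counts.mean(), 500_000 / 30)  # ~16,667 per chromosome

    def test_frequencies_uniform_goodness_of_fit(self):
        m = ldsim.make_marker_map(cfg(n_markers_total=10_000), rng=1)
        assert stats.kstest(m.freq, "uniform").pvalue > 0.01

    def test_rejects_fewer_markers_than_chromosomes(self):
        with pytest.raises(ValueError):
            ldsim.SimConfig(n_chromosomes=10, n_markers_total=5)

    def test_first_marker_of_each_chromosome_has_no_phase_sign(self):
        m = ldsim.make_marker_map(cfg(n_chromosomes=4, n_markers_total=100), rng=2)
        starts, _ = m.chrom_bounds()
        assert not m.repulsion[starts].any()


class TestFounders:
    def test_no_break_limit_gives_single_phase_linked_block(self):
        c = cfg(n_markers_total=50, ld_decay=1.0)
        m = ldsim.make_marker_map(c, rng=3)
        m.freq[:] = 0.5
        H = ldsim.simulate_founders(m, c, 200, rng=3)
        # with one block per chromosome, every haplotype follows the phase
        # chain exactly: alleles are determined by the first allele
        flips = np.cumsum(m.repulsion.astype(int)) % 2
        expect0 = np.where(flips == 0, H[:, :1], 2 - H[:, :1])
        assert np.array_equal(H, expect0)

    def test_zero_decay_gives_independent_adjacent_markers(self):
        c = cfg(n_markers_total=30, ld_decay=0.0)
        m = ldsim.make_marker_map(c, rng=4)
        m.freq[:] = 0.5
        H = ldsim.simulate_founders(m, c, 5000, rng=4).astype(float)
        r = np.corrcoef(H.T)
        adj = np.diag(r, k=1)
        assert np.abs(adj).max() < 0.06  # ~4 SE at n=5000

    def test_minor_allele_frequency_matches_target(self):
        c = cfg(n_markers_total=200, ld_decay=0.9)
        m = ldsim.make_marker_map(c, rng=5)
        H = ldsim.simulate_founders(m, c, 20_000, rng=5)
        f2 = (H == 2).mean(axis=0)
        se = np.sqrt(m.freq * (1 - m.freq) / 20_000)
        outside = np.abs(f2 - m.freq) > 3 * se
        # ~0.27% of loci expected outside 3 SE; allow a small margin
        assert outside.sum() <= 4

    def test_ld_decays_with_distance(self):
        c = cfg(n_markers_total=500, ld_decay=0.99)
        m = ldsim.make_marker_map(c, rng=6)
        H = ldsim.simulate_founders(m, c, 2000, rng=6).astype(float)
        from herd.metrics import ld_r2_by_distance
        curve = ld_r2_by_distance(H, m, bins=[0, 0.02, 0.08, 0.3, 1.0], seed=0)
        r2 = curve["mean_r2"].to_numpy()
        assert np.all(np.diff(r2) <= 0)


@pytest.fixture(scope="module")
def family():
    c = cfg(n_chromosomes=2, n_markers_total=400)
    m = ldsim.make_marker_map(c, rng=7)
    ped = ldsim.Pedigree(
        ids=np.array(["S", "D", *[f"C{i}" for i in range(30)]], dtype=object),
        sire=np.array([-1, -1] + [0] * 30, dtype=np.int32),
        dam=np.array([-1, -1] + [1] * 30, dtype=np.int32),
        cohort=np.full(32, int(ldsim.Cohort.ANCESTOR), np.int8),
        density=np.full(32, int(ldsim.Density.HIGH), np.int8))
    founders = ldsim.simulate_founders(m, c, 4, rng=7)
    genome = ldsim.drop_pedigree(ped, founders, m, c, rng=7)
    return c, m, ped, genome


class TestGeneDrop:
    def test_every_progeny_allele_comes_from_a_parent(self, family):
        _, _, ped, genome = family
        H = genome.haplotypes
        for child in range(2, 32):
            assert np.all((H[child, 0] == H[0, 0]) | (H[child, 0] == H[0, 1]))
            assert np.all((H[child, 1] == H[1, 0]) | (H[child, 1] == H[1, 1]))

    def test_homozygous_parent_always_transmits_its_allele(self, family):
        _, _, _, genome = family
        H = genome.haplotypes
        hom = H[0, 0] == H[0, 1]
        for child in range(2, 32):
            assert np.array_equal(H[child, 0][hom], H[0, 0][hom])

    def test_mean_crossovers_per_morgan_is_one(self):
        c = cfg(n_markers_total=2000)
        m = ldsim.make_marker_map(c, rng=8)
        rng = np.random.default_rng(8)
        pat = np.zeros(2000, dtype=np.int8)
        mat = np.full(2000, 2, dtype=np.int8)  # fully informative meiosis
        starts, stops = m.chrom_bounds()
        n = 10_000
        xovers = np.empty(n)
        from herd.ldsim import _meiosis
        for i in range(n):
            g = _meiosis(pat, mat, m, rng, starts, stops, 1.0)
            xovers[i] = np.count_nonzero(np.diff(g) != 0)
        se = xovers.std(ddof=1) / np.sqrt(n)
        assert abs(xovers.mean() - 1.0) < 3 * se

    def test_cycle_is_rejected_with_chain(self):
        with pytest.raises(ValueError, match="cycle"):
            ldsim.Pedigree(ids=np.array(["a", "b"], dtype=object),
                           sire=np.array([1, 0], np.int32),
                           dam=np.array([-1, -1], np.int32),
                           cohort=np.zeros(2, np.int8),
                           density=np.zeros(2, np.int8))


class TestQTL:
    def test_transform_is_odd_and_kills_zero(self):
        s = np.array([0.0, 1.5, -1.5])
        a = s * np.exp2(np.abs(s) - 2.0)
        assert a[0] == 0.0
        assert a[1] == -a[2] != 0

    def test_effects_rescaled_to_additive_variance(self):
        c = cfg(n_chromosomes=2, n_markers_total=200, n_qtl=500, sigma_a2=2.5)
        m = ldsim.make_marker_map(c, rng=9)
        q = ldsim.place_qtl(m, c, rng=9)
        q, _ = ldsim.simulate_qtl_effects(q, c, rng=9)
        assert np.isclose(np.sum(2 * q.freq * (1 - q.freq) * q.effect ** 2), 2.5)

    def test_qtl_sit_strictly_between_markers(self):
        c = cfg(n_markers_total=50, n_qtl=200)
        m = ldsim.make_marker_map(c, rng=10)
        q = ldsim.place_qtl(m, c, rng=10)
        assert not np.isin(q.position, m.position).any()
        assert q.position.min() > m.position.min()
        assert q.position.max() < m.position.max()

    def test_tbv_variance_matches_sigma_a2(self):
        c = ldsim.SimConfig(n_chromosomes=3, n_markers_total=300, n_qtl=2000,
                            sigma_a2=1.0)
        rng = np.random.default_rng(11)
        m = ldsim.make_marker_map(c, rng)
        q = ldsim.place_qtl(m, c, rng)
        loci, is_marker = ldsim.merge_loci(m, q)
        H = ldsim.simulate_founders(loci, c, 6000, rng)
        qd = ((H[0::2, ~is_marker] + H[1::2, ~is_marker]) // 2).astype(np.int8)
        q, tbv = ldsim.simulate_qtl_effects(q, c, rng, qtl_dosage=qd)
        assert abs(np.var(tbv) - 1.0) < 0.10


class TestPhenotypes:
    @pytest.mark.parametrize("rel,expected", [(0.5, 1.0), (0.3, 2.3333), (0.999, 0.001001)])
    def test_error_variance_formula(self, rel, expected):
        assert ldsim.error_variance(rel) == pytest.approx(expected, rel=1e-3)

    def test_reliability_outside_unit_interval_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                ldsim.error_variance(bad)

    def test_only_recorded_cohorts_receive_records(self):
        sc = ldsim.simulate_population(
            ldsim.SimConfig(n_chromosomes=1, n_markers_total=60, n_qtl=30),
            seed=12, n_proven=20, n_young=30, n_cows=10, n_heifers=10,
            n_ancestor_generations=2, males_per_generation=4,
            females_per_generation=15)
        got = set(sc.pedigree.cohort[sc.phenotypes["animal_index"]])
        assert got <= {int(ldsim.Cohort.PROVEN_BULL), int(ldsim.Cohort.COW)}


class TestArtifacts:
    def test_zero_rates_are_identity(self):
        truth = np.random.default_rng(0).integers(0, 3, (20, 50)).astype(np.int8)
        c = cfg(missing_rate=0.0, read_error_rate=0.0)
        gm = ldsim.apply_genotyping_artifacts(truth, c, rng=0)
        assert np.array_equal(gm.codes, truth)
        assert not gm.missing.any()

    def test_all_missing_at_rate_one(self):
        truth = np.ones((5, 10), dtype=np.int8)
        gm = ldsim.apply_genotyping_artifacts(truth, cfg(missing_rate=1.0), rng=0)
        assert gm.missing.all()

    def test_missing_rate_calibration(self):
        truth = np.random.default_rng(1).integers(0, 3, (500, 10_000)).astype(np.int8)
        c = cfg(missing_rate=0.0100, read_error_rate=0.0002)
        gm = ldsim.apply_genotyping_artifacts(truth, c, rng=1)
        n = truth.size
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(gm.missing.mean() - 0.0100) < 3 * se
        err = (gm.codes != truth) & ~gm.missing
        se_e = np.sqrt(0.0002 * 0.9998 / n)
        assert abs(err.mean() - 0.0002) < 3 * se_e

    def test_read_errors_change_the_code(self):
        truth = np.zeros((200, 200), dtype=np.int8)
        gm = ldsim.apply_genotyping_artifacts(truth, cfg(read_error_rate=0.5), rng=2)
        changed = (~gm.missing) & (gm.codes != 0)
        assert changed.any()
        assert np.isin(gm.codes[changed], (1, 2)).all()


class TestMasking:
    def test_every_tenth_marker_retained(self):
        c = cfg(n_markers_total=20)
        m = ldsim.make_marker_map(c, rng=13)
        codes = np.zeros((2, 20), dtype=np.int8)
        gm = ldsim.GenotypeMatrix(codes, np.zeros_like(codes, bool))
        density = np.array([int(ldsim.Density.LOW), int(ldsim.Density.HIGH)], np.int8)
        out, mask = ldsim.mask_low_density(gm, density, m, keep_every=10)
        assert np.array_equal(np.flatnonzero(~out.missing[0]), [0, 10])
        assert not out.missing[1].any()
        assert mask.sum() == 18

    def test_keep_every_one_is_identity(self):
        c = cfg(n_markers_total=15)
        m = ldsim.make_marker_map(c, rng=14)
        codes = np.ones((1, 15), dtype=np.int8)
        gm = ldsim.GenotypeMatrix(codes, np.zeros_like(codes, bool))
        out, mask = ldsim.mask_low_density(gm, np.array([1], np.int8), m, keep_every=1)
        assert not mask.any()
        assert np.array_equal(out.codes, gm.codes)

    def test_full_design_retains_fifty_thousand_markers(self):
        # every 10th of 500,000 markers leaves 50,000 observed
        keep = np.arange(500_000) % 10 == 0
        assert keep.sum() == 50_000


class TestDeterminism:
    def test_identical_seed_reproduces_scenario_bit_for_bit(self):
        kw = dict(n_proven=15, n_young=20, n_cows=8, n_heifers=7,
                  n_ancestor_generations=2, males_per_generation=4,
                  females_per_generation=12)
        c = ldsim.SimConfig(n_chromosomes=1, n_markers_total=80, n_qtl=20)
        a = ldsim.simulate_population(c, seed=99, **kw)
        b = ldsim.simulate_population(c, seed=99, **kw)
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        assert np.array_equal(a.genotypes.missing, b.genotypes.missing)
        assert np.array_equal(a.truth.haplotypes, b.truth.haplotypes)
        assert np.allclose(a.tbv, b.tbv)
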