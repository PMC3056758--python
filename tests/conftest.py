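import numpy as np
import pytest

from herd import ldsim
from herd.haplotyper import HaplotypeImputer


@pytest.fixture(scope="session")
def mixed_run():
    """The scaled mixed-density study: ~2,000 genotyped animals over
    3 chromosomes x 2,000 markers, heavy-use sires plus ~10% of animals at
    full density, the rest masked to every 10th marker; imputed with the
    six-iteration schedule."""
    scenario = ldsim.simulate_population(seed=1, mixed_density=True)
    imputer = HaplotypeImputer(pedigree=scenario.pedigree,
                               marker_map=scenario.marker_map, segment_size=500)
    imputer.fit(scenario.genotypes)
    return scenario, imputer


@pytest.fixture(scope="session")
def small_run():
    """A fast, small single-density scenario with truth, for metric and
    invariant tests."""
    config = ldsim.SimConfig(n_chromosomes=2, n_markers_total=600, n_qtl=0)
    scenario = ldsim.simulate_population(
        config, seed=5, n_proven=60, n_young=90, n_cows=30, n_heifers=30,
        n_ancestor_generations=5, males_per_generation=6, females_per_generation=40)
    imputer = HaplotypeImputer(pedigree=scenario.pedigree,
                               marker_map=scenario.marker_map, segment_size=100)
    imputer.fit(scenario.genotypes)
    return scenario, imputer


@pytest.fixture(scope="session")
def eval_scenario():
    """Genotypes + QTL positions for evaluation experiments; traits (QTL
    effect replicates) are drawn per test on this one genotype set."""
    config = ldsim.SimConfig(n_chromosomes=2, n_markers_total=400, n_qtl=200, seed=7)
    return ldsim.simulate_population(
        config, seed=7, n_proven=250, n_young=200, n_cows=150, n_heifers=0,
        n_ancestor_generations=6, males_per_generation=8, females_per_generation=50)


def draw_trait(scenario, rng):
    """One replicate trait: heavy-tailed QTL effects, TBV, deregressed records."""
    ped = scenario.pedigree
    rec = np.isin(ped.cohort, [int(ldsim.Cohort.PROVEN_BULL), int(ldsim.Cohort.COW)])
    rec_idx = np.flatnonzero(rec)
    _, tbv = ldsim.simulate_qtl_effects(scenario.qtl, scenario.config, rng,
                                        qtl_dosage=scenario.qtl_dosage)
    rel = np.where(ped.cohort[rec_idx] == int(ldsim.Cohort.PROVEN_BULL),
                   rng.uniform(0.85, 0.99, rec_idx.size),
                   rng.uniform(0.25, 0.40, rec_idx.size))
    y = tbv[rec_idx] + rng.normal(0.0, np.sqrt(1.0 / rel - 1.0))
    return tbv, rec_idx, y, rel
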