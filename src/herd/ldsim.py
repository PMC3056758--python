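"""Simulation of genotypes with built-in linkage disequilibrium.

The generator creates founder haplotypes whose alleles are correlated along
the chromosome through an autoregressive block process (one parameter, the LD
decay per adjacent locus), gene-drops them through an arbitrary pedigree with
Haldane (no-interference) recombination, attaches heavy-tailed QTL effects,
simulates deregressed phenotypes with heterogeneous error variance, and
finally applies genotyping artifacts (missing entries, read errors) and
low-density masking.

Alleles on haplotypes are coded 0 and 2 so that a genotype code is simply the
mean of the two haplotype codes: 0 and 2 are the homozygotes and 1 the
heterozygote, the convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "Density",
    "SimConfig",
    "MarkerMap",
    "QTLSet",
    "Pedigree",
    "TrueGenome",
    "GenotypeMatrix",
    "Scenario",
    "make_marker_map",
    "place_qtl",
    "simulate_founders",
    "drop_pedigree",
    "simulate_qtl_effects",
    "simulate_phenotypes",
    "apply_genotyping_artifacts",
    "mask_low_density",
    "simulate_population",
]


class Cohort(IntEnum):
    """Population groups mirroring a progeny-testing dairy scheme."""

    ANCESTOR = 0      # non-genotyped pedigree ancestors
    PROVEN_BULL = 1   # progeny-tested bulls with phenotype records
    YOUNG_BULL = 2    # genotyped young bulls, no records yet
    COW = 3           # cows with own records
    HEIFER = 4        # young females, no records


class Density(IntEnum):
    NONE = 0  # not genotyped
    LOW = 1   # reduced panel (every k-th marker)
    HIGH = 2  # full panel


#: cohorts that carry a phenotype record ("old" animals)
RECORDED_COHORTS = (Cohort.PROVEN_BULL, Cohort.COW)


@dataclass
class SimConfig:
    """Parameters of the genome/population simulation.

    ``ld_decay`` is the probability that a founder haplotype block continues
    between adjacent underlying loci; 0.998 gives blocks of ~500 loci.
    ``missing_rate`` and ``read_error_rate`` are per-entry genotyping artifact
    probabilities.  ``sigma_a2`` is the additive genetic variance to which QTL
    effects are rescaled.
    """

    n_chromosomes: int = 30
    chromosome_length: float = 1.0  # Morgans
    n_markers_total: int = 500_000
    ld_decay: float = 0.998
    missing_rate: float = 0.0100
    read_error_rate: float = 0.0002
    n_qtl: int = 10_000
    sigma_a2: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("ld_decay", "missing_rate", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_markers_total < self.n_chromosomes:
            raise ValueError(
                "n_markers_total must be at least n_chromosomes "
                f"({self.n_markers_total} < {self.n_chromosomes})"
            )
        if self.sigma_a2 <= 0:
            raise ValueError("sigma_a2 must be positive")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")


@dataclass
class LocusTable:
    """Per-locus simulation properties, sorted by (chromosome, position).

    Used both for marker maps and for the merged marker+QTL genome.
    ``repulsion[i]`` links locus ``i`` to its predecessor on the same
    chromosome (True = opposite underlying allele); it is undefined (False)
    for the first locus of each chromosome.  ``freq`` is the target frequency
    of allele "2".
    """

    chrom: np.ndarray       # int32
    position: np.ndarray    # float64, Morgans
    freq: np.ndarray        # float64 in (0, 1)
    repulsion: np.ndarray   # bool

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.position = np.asarray(self.position, dtype=np.float64)
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.repulsion = np.asarray(self.repulsion, dtype=bool)
        if not (len(self.chrom) == len(self.position) == len(self.freq) == len(self.repulsion)):
            raise ValueError("locus arrays must have equal length")
        if np.any((self.freq <= 0) | (self.freq >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for lo, hi in zip(*self.chrom_bounds()):
            if np.any(np.diff(self.position[lo:hi]) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    def chrom_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Start/stop index of each chromosome's loci (half-open ranges)."""
        chroms = np.unique(self.chrom)
        starts = np.searchsorted(self.chrom, chroms, side="left")
        stops = np.searchsorted(self.chrom, chroms, side="right")
        return starts, stops

    def local_index(self) -> np.ndarray:
        """0-based index of each locus within its own chromosome."""
        out = np.arange(len(self), dtype=np.int64)
        starts, stops = self.chrom_bounds()
        for lo, hi in zip(starts, stops):
            out[lo:hi] -= lo
        return out


@dataclass
class MarkerMap(LocusTable):
    """Marker map: chromosome, map position, target allele frequency."""

    @property
    def n_markers(self) -> int:
        return len(self.chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "marker_id": [f"M{i + 1}" for i in range(len(self))],
                "position_morgans": self.position,
                "allele_freq": self.freq,
            }
        )


@dataclass
class QTLSet:
    """QTL placed strictly between adjacent markers.

    ``s`` is the standard normal draw and ``effect`` the heavy-tailed,
    variance-rescaled allele substitution effect a = s * 2**(|s| - 2) * c.
    """

    chrom: np.ndarray
    position: np.ndarray
    freq: np.ndarray
    repulsion: np.ndarray
    s: np.ndarray = field(default=None)  # type: ignore[assignment]
    effect: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_qtl(self) -> int:
        return len(self.chrom)


@dataclass
class Pedigree:
    """Pedigree with integer parent indices (-1 = unknown parent).

    ``topo_order`` lists animal indices parents-before-progeny; construction
    fails on cycles (see :func:`herd.io.read_pedigree` for file input).
    """

    ids: np.ndarray          # object/str array
    sire: np.ndarray         # int32 index into ids, -1 unknown
    dam: np.ndarray
    cohort: np.ndarray       # int8 Cohort codes
    density: np.ndarray      # int8 Density codes

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int32)
        self.dam = np.asarray(self.dam, dtype=np.int32)
        self.cohort = np.asarray(self.cohort, dtype=np.int8)
        self.density = np.asarray(self.density, dtype=np.int8)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate animal ids in pedigree")
        self._topo = self._toposort()

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def _toposort(self) -> np.ndarray:
        """Kahn topological order; raises with the offending chain on a cycle."""
        n = self.n_animals
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for a in range(n):
            for p in (self.sire[a], self.dam[a]):
                if p >= 0:
                    if p >= n:
                        raise ValueError(f"dangling parent index {p} for animal {self.ids[a]}")
                    children[p].append(a)
                    indeg[a] += 1
        order: list[int] = []
        stack = [a for a in range(n) if indeg[a] == 0]
        while stack:
            a = stack.pop()
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != n:
            # recover one cycle for the error message
            import networkx as nx

            g = nx.DiGraph()
            for a in range(n):
                for p in (self.sire[a], self.dam[a]):
                    if p >= 0:
                        g.add_edge(int(p), int(a))
            cycle = nx.find_cycle(g)
            chain = " -> ".join(str(self.ids[e[0]]) for e in cycle) + f" -> {self.ids[cycle[-1][1]]}"
            raise ValueError(f"pedigree contains a cycle: {chain}")
        return np.asarray(order, dtype=np.int64)

    @property
    def topo_order(self) -> np.ndarray:
        return self._topo

    def genotyped(self) -> np.ndarray:
        return np.asarray(self.density, dtype=np.int8) != int(Density.NONE)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        return np.asarray([lookup[a] for a in ids], dtype=np.int64)


@dataclass
class TrueGenome:
    """True phased haplotypes over marker loci, alleles coded {0, 2}.

    ``haplotypes[a, 0]`` is the paternal and ``haplotypes[a, 1]`` the maternal
    haplotype of animal ``a``.
    """

    haplotypes: np.ndarray  # (n_animals, 2, n_loci) int8

    def dosage(self) -> np.ndarray:
        """Genotype codes 0/1/2 (= count of allele 2)."""
        return ((self.haplotypes[:, 0, :] + self.haplotypes[:, 1, :]) // 2).astype(np.int8)


@dataclass
class GenotypeMatrix:
    """Observed genotypes: codes {0,1,2} with a missing mask.

    Missing entries carry matching code 1 ("heterozygous or not known") so the
    same conflict arithmetic applies everywhere.
    """

    codes: np.ndarray    # int8, missing entries stored as 1
    missing: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.codes.shape != self.missing.shape:
            raise ValueError("codes and missing mask must have the same shape")
        if np.any(self.codes[self.missing] != 1):
            raise ValueError("masked entries must carry matching code 1")
        bad = ~np.isin(self.codes, (0, 1, 2))
        if np.any(bad):
            raise ValueError("genotype codes must be 0, 1 or 2")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.copy(), self.missing.copy())


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# marker map and QTL placement
# ---------------------------------------------------------------------------

def make_marker_map(config: SimConfig, rng=None) -> MarkerMap:
    """Allocate markers across chromosomes and draw positions/frequencies.

    Counts are near-equal per chromosome; positions are uniform on
    [0, chromosome_length) and sorted; frequencies uniform on (0, 1); the
    linkage-phase direction to the previous marker is coupling or repulsion
    with probability 0.5 each.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    counts = np.full(config.n_chromosomes, config.n_markers_total // config.n_chromosomes)
    counts[: config.n_markers_total % config.n_chromosomes] += 1
    chrom, pos = [], []
    for c, k in enumerate(counts):
        p = np.sort(rng.random(k)) * config.chromosome_length
        # duplicate positions are measure-zero; nudge them apart if they occur
        dup = np.flatnonzero(np.diff(p) == 0)
        if dup.size:
            p[dup + 1] = np.nextafter(p[dup + 1], np.inf)
        chrom.append(np.full(k, c, dtype=np.int32))
        pos.append(p)
    n = config.n_markers_total
    freq = rng.random(n)
    freq = np.clip(freq, 1e-9, 1 - 1e-9)
    repulsion = rng.random(n) < 0.5
    m = MarkerMap(np.concatenate(chrom), np.concatenate(pos), freq, repulsion)
    starts, _ = m.chrom_bounds()
    m.repulsion[starts] = False
    return m


def place_qtl(marker_map: MarkerMap, config: SimConfig, rng=None) -> QTLSet:
    """Place QTL strictly between adjacent markers (never on a marker).

    Gaps are chosen uniformly among within-chromosome marker intervals, and
    the QTL sits uniformly inside its gap.  QTL allele frequencies are uniform
    on (0, 1), linkage-phase signs Bernoulli(0.5), like markers.
    """
    rng = _as_rng(rng)
    starts, stops = marker_map.chrom_bounds()
    gap_left = np.concatenate(
        [np.arange(lo, hi - 1) for lo, hi in zip(starts, stops) if hi - lo >= 2]
    )
    if gap_left.size == 0:
        raise ValueError("need at least two markers on some chromosome to place QTL")
    pick = rng.integers(0, gap_left.size, size=config.n_qtl)
    left = gap_left[pick]
    lo_pos = marker_map.position[left]
    hi_pos = marker_map.position[left + 1]
    u = rng.random(config.n_qtl)
    pos = lo_pos + u * (hi_pos - lo_pos)
    # keep strictly inside the open interval
    pos = np.clip(pos, np.nextafter(lo_pos, np.inf), np.nextafter(hi_pos, -np.inf))
    chrom = marker_map.chrom[left]
    order = np.lexsort((pos, chrom))
    freq = np.clip(rng.random(config.n_qtl), 1e-9, 1 - 1e-9)
    repulsion = rng.random(config.n_qtl) < 0.5
    return QTLSet(chrom[order].copy(), pos[order], freq, repulsion)


def merge_loci(marker_map: MarkerMap, qtl: QTLSet | None) -> tuple[LocusTable, np.ndarray]:
    """Interleave markers and QTL into one sorted locus table.

    Returns the merged table and a boolean mask selecting marker columns.
    Repulsion signs are redrawn relative to the *merged* predecessor by
    keeping each locus's own stored sign; because signs are i.i.d.
    Bernoulli(0.5), re-anchoring them to a different predecessor preserves the
    model.
    """
    if qtl is None or qtl.n_qtl == 0:
        return (
            LocusTable(marker_map.chrom, marker_map.position, marker_map.freq, marker_map.repulsion),
            np.ones(len(marker_map), dtype=bool),
        )
    chrom = np.concatenate([marker_map.chrom, qtl.chrom])
    pos = np.concatenate([marker_map.position, qtl.position])
    freq = np.concatenate([marker_map.freq, qtl.freq])
    rep = np.concatenate([marker_map.repulsion, qtl.repulsion])
    is_marker = np.concatenate(
        [np.ones(len(marker_map), dtype=bool), np.zeros(qtl.n_qtl, dtype=bool)]
    )
    order = np.lexsort((pos, chrom))
    table = LocusTable(chrom[order], pos[order], freq[order], rep[order])
    starts, _ = table.chrom_bounds()
    table.repulsion[starts] = False
    return table, is_marker[order]


# ---------------------------------------------------------------------------
# founder haplotypes with built-in LD
# ---------------------------------------------------------------------------

def simulate_founders(loci: LocusTable, config: SimConfig, n_haplotypes: int, rng=None) -> np.ndarray:
    """Simulate founder haplotypes with autoregressive LD blocks.

    For each haplotype and chromosome the first *underlying* allele is
    Bernoulli(0.5); each next locus copies the previous underlying allele
    (flipped under repulsion phase) unless the block breaks, which happens
    with probability ``1 - ld_decay`` per step.  One uniform ``u`` is drawn
    per block: at each locus the *observed* allele is the major allele when
    ``u > 2 * MAF(locus)``, otherwise the underlying allele.  This replacement
    rule reproduces the target minor allele frequency exactly.

    Returns an int8 array of shape (n_haplotypes, n_loci) with alleles {0, 2}.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    n_loci = len(loci)
    out = np.empty((n_haplotypes, n_loci), dtype=np.int8)
    maf = np.minimum(loci.freq, 1.0 - loci.freq)
    major_is_2 = loci.freq > 0.5
    starts, stops = loci.chrom_bounds()
    for lo, hi in zip(starts, stops):
        L = hi - lo
        breaks = rng.random((n_haplotypes, L)) > config.ld_decay
        breaks[:, 0] = True
        # index of each locus's block start
        idx = np.where(breaks, np.arange(L)[None, :], 0)
        start_idx = np.maximum.accumulate(idx, axis=1)
        # cumulative phase flips along the chromosome (shared by all haplotypes)
        flips = np.cumsum(loci.repulsion[lo:hi].astype(np.int8)) & 1
        bits = rng.integers(0, 2, size=(n_haplotypes, L), dtype=np.int8)
        rows = np.arange(n_haplotypes)[:, None]
        base = bits[rows, start_idx]
        underlying = base ^ (flips[None, :] ^ flips[start_idx])
        # one uniform per block, shared by all loci of the block
        u_all = rng.random((n_haplotypes, L))
        u = u_all[rows, start_idx]
        keep = u <= 2.0 * maf[lo:hi][None, :]
        allele2 = np.where(keep, underlying == 1, major_is_2[lo:hi][None, :])
        out[:, lo:hi] = np.where(allele2, 2, 0).astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# gene drop through the pedigree
# ---------------------------------------------------------------------------

def _meiosis(pat: np.ndarray, mat: np.ndarray, loci: LocusTable, rng: np.random.Generator,
             starts: np.ndarray, stops: np.ndarray, length: float) -> np.ndarray:
    """One gamete from a parent: Haldane model, Poisson(length) crossovers."""
    gamete = np.empty_like(pat)
    for lo, hi in zip(starts, stops):
        k = rng.poisson(length)
        first = rng.integers(0, 2)
        if k == 0:
            src = pat if first == 0 else mat
            gamete[lo:hi] = src[lo:hi]
            continue
        xpos = np.sort(rng.random(k) * length)
        n_before = np.searchsorted(xpos, loci.position[lo:hi], side="right")
        use_mat = (n_before + first) & 1
        gamete[lo:hi] = np.where(use_mat == 0, pat[lo:hi], mat[lo:hi])
    return gamete


def drop_pedigree(pedigree: Pedigree, founders: np.ndarray, loci: LocusTable,
                  config: SimConfig, rng=None) -> TrueGenome:
    """Gene-drop founder haplotypes through the pedigree.

    Every gamete from an unknown parent consumes a fresh founder haplotype (in
    order); gametes from known parents are recombinants of the parent's two
    haplotypes.  QTL loci, if present in ``loci``, inherit exactly like
    markers.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    n = pedigree.n_animals
    n_loci = len(loci)
    H = np.zeros((n, 2, n_loci), dtype=np.int8)
    starts, stops = loci.chrom_bounds()
    next_founder = 0
    for a in pedigree.topo_order:
        for slot, parent in ((0, pedigree.sire[a]), (1, pedigree.dam[a])):
            if parent < 0:
                if next_founder >= founders.shape[0]:
                    raise ValueError(
                        "founder pool exhausted: need one haplotype per unknown-parent gamete"
                    )
                H[a, slot] = founders[next_founder]
                next_founder += 1
            else:
                H[a, slot] = _meiosis(
                    H[parent, 0], H[parent, 1], loci, rng, starts, stops,
                    config.chromosome_length,
                )
    return TrueGenome(H)


def n_founder_haplotypes_needed(pedigree: Pedigree) -> int:
    return int(np.sum(pedigree.sire < 0) + np.sum(pedigree.dam < 0))


# ---------------------------------------------------------------------------
# QTL effects, TBV, phenotypes
# ---------------------------------------------------------------------------

def simulate_qtl_effects(qtl: QTLSet, config: SimConfig, rng=None,
                         qtl_dosage: np.ndarray | None = None) -> tuple[QTLSet, np.ndarray | None]:
    """Draw heavy-tailed QTL effects and (optionally) true breeding values.

    Standard normal draws ``s`` are transformed sign-preservingly to
    ``a = s * 2**(|s| - 2)`` and rescaled so the expected additive variance
    ``sum_j 2 p_j q_j a_j**2`` equals ``sigma_a2``.  If a QTL allele-count
    matrix (animals x QTL, counts of allele 2 in {0,1,2}) is given, centered
    TBVs are returned as well.
    """
    rng = _as_rng(rng)
    s = rng.standard_normal(qtl.n_qtl)
    a = s * np.exp2(np.abs(s) - 2.0)
    denom = np.sum(2.0 * qtl.freq * (1.0 - qtl.freq) * a ** 2)
    a = a * np.sqrt(config.sigma_a2 / denom)
    out = replace(qtl, s=s, effect=a)
    tbv = None
    if qtl_dosage is not None:
        tbv = qtl_dosage @ a
        tbv = tbv - tbv.mean()
    return out, tbv


def simulate_phenotypes(tbv: np.ndarray, pedigree: Pedigree, config: SimConfig, rng=None,
                        bull_rel: tuple[float, float] = (0.85, 0.99),
                        cow_rel: tuple[float, float] = (0.25, 0.40)) -> pd.DataFrame:
    """Deregressed observations for recorded cohorts (proven bulls, cows).

    y_i = TBV_i + e_i with Var(e_i) = sigma_a2 * (1/REL_prog - 1).  Proven
    bulls draw REL_prog from ``bull_rel`` (progeny-test information), cows
    from ``cow_rel`` (one or a few own records at moderate heritability).
    """
    rng = _as_rng(rng)
    rows = []
    for a in range(pedigree.n_animals):
        co = Cohort(pedigree.cohort[a])
        if co not in RECORDED_COHORTS:
            continue
        lo, hi = bull_rel if co == Cohort.PROVEN_BULL else cow_rel
        rel = rng.uniform(lo, hi)
        if not 0.0 < rel < 1.0:
            raise ValueError("REL_prog must lie strictly in (0, 1)")
        ev = config.sigma_a2 * (1.0 / rel - 1.0)
        y = tbv[a] + rng.normal(0.0, np.sqrt(ev))
        rows.append((a, pedigree.ids[a], y, rel, ev))
    return pd.DataFrame(rows, columns=["animal_index", "animal_id", "y", "rel_prog", "error_variance"])


def error_variance(rel_prog: float, sigma_a2: float = 1.0) -> float:
    """sigma_a2 * (1/REL_prog - 1); rejects REL_prog outside (0, 1)."""
    if not 0.0 < rel_prog < 1.0:
        raise ValueError(f"REL_prog must be in (0, 1), got {rel_prog}")
    return sigma_a2 * (1.0 / rel_prog - 1.0)


# ---------------------------------------------------------------------------
# genotyping artifacts and density masking
# ---------------------------------------------------------------------------

def apply_genotyping_artifacts(true_dosage: np.ndarray, config: SimConfig, rng=None,
                               genotyped: np.ndarray | None = None) -> GenotypeMatrix:
    """Apply i.i.d. missingness and read errors to a true genotype matrix.

    Each entry is set missing with probability ``missing_rate``; each
    surviving entry is replaced by a uniformly chosen *different* code with
    probability ``read_error_rate``.  Rows of non-genotyped animals (mask
    ``genotyped`` False) are entirely missing.
    """
    rng = _as_rng(rng)
    codes = np.asarray(true_dosage, dtype=np.int8).copy()
    missing = rng.random(codes.shape) < config.missing_rate
    if config.read_error_rate > 0:
        err = (~missing) & (rng.random(codes.shape) < config.read_error_rate)
        shift = rng.integers(1, 3, size=int(err.sum()))
        codes[err] = ((codes[err] + shift) % 3).astype(np.int8)
    if genotyped is not None:
        missing[~np.asarray(genotyped, dtype=bool), :] = True
    codes[missing] = 1
    return GenotypeMatrix(codes, missing)


def mask_low_density(genotypes: GenotypeMatrix, density: np.ndarray, marker_map: MarkerMap,
                     keep_every: int = 10) -> tuple[GenotypeMatrix, np.ndarray]:
    """Reduce low-density animals to every ``keep_every``-th marker.

    Within each chromosome, markers whose local index is not a multiple of
    ``keep_every`` are set missing for animals with density LOW.  Returns the
    masked matrix and the boolean mask of entries removed by this step.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    out = genotypes.copy()
    low = np.asarray(density, dtype=np.int8) == int(Density.LOW)
    drop_marker = marker_map.local_index() % keep_every != 0
    mask = np.zeros(out.codes.shape, dtype=bool)
    mask[np.ix_(low, drop_marker)] = True
    out.codes[mask] = 1
    out.missing |= mask
    return out, mask


# ---------------------------------------------------------------------------
# scaled population scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully simulated study population (inputs plus truth)."""

    config: SimConfig
    pedigree: Pedigree
    marker_map: MarkerMap
    truth: TrueGenome                  # marker haplotypes, all animals
    genotypes: GenotypeMatrix          # after artifacts (and masking if mixed)
    qtl: QTLSet | None = None
    qtl_dosage: np.ndarray | None = None  # animals x QTL allele-2 counts
    tbv: np.ndarray | None = None
    phenotypes: pd.DataFrame | None = None
    density_mask: np.ndarray | None = None  # entries removed by low-density masking

    @property
    def old_mask(self) -> np.ndarray:
        """Animals with phenotype records ('old'); complement of genotyped = 'young'."""
        return np.isin(self.pedigree.cohort, [int(c) for c in RECORDED_COHORTS])


def _zipf_weights(n: int, exponent: float = 1.1) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=np.float64) ** (-exponent)
    return w / w.sum()


def _default_scaled_config() -> SimConfig:
    # desk-scale genome: 3 chromosomes x 2,000 markers.  The chromosome
    # length preserves the full-scale marker density (16,667 markers per
    # Morgan), so both LD per marker interval and recombination per
    # 500-marker segment match the full-size design.
    return SimConfig(n_chromosomes=3, n_markers_total=6000, n_qtl=0,
                     chromosome_length=2000.0 / 16_667.0)


def simulate_population(config: SimConfig | None = None, *,
                        n_proven: int = 540, n_young: int = 840,
                        n_cows: int = 260, n_heifers: int = 360,
                        n_ancestor_generations: int = 8,
                        males_per_generation: int = 25,
                        females_per_generation: int = 200,
                        n_founder_males: int | None = None,
                        n_founder_females: int | None = None,
                        sire_popularity: float = 1.0,
                        mixed_density: bool = False, keep_every: int = 10,
                        high_density_fraction: float = 0.10,
                        min_progeny_high: int = 10,
                        seed: int | None = None) -> Scenario:
    """Simulate the scaled progeny-test population.

    Cohort sizes default to a ~2,000-animal population in the proportions of a
    large Holstein scheme (proven bulls : young bulls : cows : heifers of
    roughly 27:42:13:18), under ``n_ancestor_generations`` of non-genotyped
    ancestors with half-sib families concentrated on a few popular sires
    (Zipf-weighted sire use).  The founder pool and generation depth are
    chosen so that a small number of frequent segment haplotypes accounts for
    most of the population — the sharing structure of an intensively selected
    dairy breed that pedigree/population haplotyping exploits.  With
    ``mixed_density=True``, heavily used
    genotyped sires (>= ``min_progeny_high`` genotyped progeny) plus randomly
    chosen young bulls up to ``high_density_fraction`` of genotyped animals
    keep the full panel; everyone else keeps every ``keep_every``-th marker.
    """
    if config is None:
        config = _default_scaled_config()
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    r_ped, r_map, r_founder, r_drop, r_qtl, r_phen, r_artifact = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    # ---- pedigree ---------------------------------------------------------
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    cohort: list[int] = []
    males_prev: list[int] = []
    females_prev: list[int] = []

    def add(id_, s, d, co):
        ids.append(id_)
        sire.append(s)
        dam.append(d)
        cohort.append(int(co))
        return len(ids) - 1

    if n_founder_males is None:
        n_founder_males = males_per_generation
    if n_founder_females is None:
        n_founder_females = females_per_generation
    for g in range(n_ancestor_generations):
        males_cur, females_cur = [], []
        if g == 0:
            for i in range(n_founder_males):
                males_cur.append(add(f"G0M{i}", -1, -1, Cohort.ANCESTOR))
            for i in range(n_founder_females):
                females_cur.append(add(f"G0F{i}", -1, -1, Cohort.ANCESTOR))
        else:
            wm = _zipf_weights(len(males_prev), sire_popularity)
            for i in range(males_per_generation):
                s = males_prev[r_ped.choice(len(males_prev), p=wm)]
                d = females_prev[r_ped.integers(len(females_prev))]
                males_cur.append(add(f"G{g}M{i}", s, d, Cohort.ANCESTOR))
            for i in range(females_per_generation):
                s = males_prev[r_ped.choice(len(males_prev), p=wm)]
                d = females_prev[r_ped.integers(len(females_prev))]
                females_cur.append(add(f"G{g}F{i}", s, d, Cohort.ANCESTOR))
        males_prev, females_prev = males_cur, females_cur

    wm = _zipf_weights(len(males_prev), sire_popularity)
    proven, cows = [], []
    for i in range(n_proven):
        s = males_prev[r_ped.choice(len(males_prev), p=wm)]
        d = females_prev[r_ped.integers(len(females_prev))]
        proven.append(add(f"PB{i}", s, d, Cohort.PROVEN_BULL))
    for i in range(n_cows):
        s = males_prev[r_ped.choice(len(males_prev), p=wm)]
        d = females_prev[r_ped.integers(len(females_prev))]
        cows.append(add(f"CW{i}", s, d, Cohort.COW))
    wp = _zipf_weights(n_proven, sire_popularity)
    for i in range(n_young):
        s = proven[r_ped.choice(n_proven, p=wp)]
        if cows and r_ped.random() < 0.7:
            d = cows[r_ped.integers(len(cows))]
        else:
            d = females_prev[r_ped.integers(len(females_prev))]
        add(f"YB{i}", s, d, Cohort.YOUNG_BULL)
    for i in range(n_heifers):
        s = proven[r_ped.choice(n_proven, p=wp)]
        if cows and r_ped.random() < 0.7:
            d = cows[r_ped.integers(len(cows))]
        else:
            d = females_prev[r_ped.integers(len(females_prev))]
        add(f"HF{i}", s, d, Cohort.HEIFER)

    cohort_arr = np.asarray(cohort, dtype=np.int8)
    sire_arr = np.asarray(sire, dtype=np.int32)
    genotyped = cohort_arr != int(Cohort.ANCESTOR)

    # ---- density assignment ----------------------------------------------
    n_animals = len(ids)
    density = np.full(n_animals, int(Density.NONE), dtype=np.int8)
    if mixed_density:
        density[genotyped] = int(Density.LOW)
        progeny_of = np.bincount(sire_arr[(sire_arr >= 0) & genotyped],
                                 minlength=n_animals)
        heavy = genotyped & (progeny_of >= min_progeny_high)
        density[heavy] = int(Density.HIGH)
        target_high = int(np.ceil(high_density_fraction * genotyped.sum()))
        need = target_high - int(heavy.sum())
        if need > 0:
            young_low = np.flatnonzero((cohort_arr == int(Cohort.YOUNG_BULL))
                                       & (density == int(Density.LOW)))
            pick = r_ped.choice(young_low, size=min(need, young_low.size), replace=False)
            density[pick] = int(Density.HIGH)
    else:
        density[genotyped] = int(Density.HIGH)

    pedigree = Pedigree(np.asarray(ids, dtype=object), sire_arr,
                        np.asarray(dam, dtype=np.int32), cohort_arr, density)

    # ---- genome -----------------------------------------------------------
    marker_map = make_marker_map(config, r_map)
    qtl = place_qtl(marker_map, config, r_qtl) if config.n_qtl > 0 else None
    loci, is_marker = merge_loci(marker_map, qtl)
    founders = simulate_founders(loci, config, n_founder_haplotypes_needed(pedigree), r_founder)
    genome = drop_pedigree(pedigree, founders, loci, config, r_drop)
    truth = TrueGenome(np.ascontiguousarray(genome.haplotypes[:, :, is_marker]))

    tbv = phenotypes = qtl_dosage = None
    if qtl is not None:
        qtl_dosage = ((genome.haplotypes[:, 0, ~is_marker]
                       + genome.haplotypes[:, 1, ~is_marker]) // 2).astype(np.int8)
        qtl, tbv = simulate_qtl_effects(qtl, config, r_qtl, qtl_dosage)
        phenotypes = simulate_phenotypes(tbv, pedigree, config, r_phen)

    # ---- observed genotypes ----------------------------------------------
    gm = apply_genotyping_artifacts(truth.dosage(), config, r_artifact, genotyped=genotyped)
    density_mask = None
    if mixed_density:
        gm, density_mask = mask_low_density(gm, density, marker_map, keep_every)

    return Scenario(config=config, pedigree=pedigree, marker_map=marker_map,
                    truth=truth, genotypes=gm, qtl=qtl, qtl_dosage=qtl_dosage,
                    tbv=tbv, phenotypes=phenotypes, density_mask=density_mask)
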