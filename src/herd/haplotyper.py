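"""Combined population and pedigree haplotyping / imputation.

Phasing works on chromosome segments.  Within a segment, a frequency-ordered
library of partially known haplotypes is grown greedily: each genotype is
matched against the list (a match = no conflict at any homozygous locus), the
matched entry is refined from the genotype's homozygous loci, the complement
haplotype is derived by subtraction and searched for in turn, and unmatched
records are appended.  Pedigree-guided iterations try parent (else
grandparent) haplotypes before scanning; the final pedigree-only iterations
rebuild each gamete from the parent's two haplotypes with a single detected
crossover, impute non-genotyped ancestors from their descendants' shared
haplotypes, and resolve single-marker parent/progeny conflicts in favour of
the more frequent haplotype.

The whole schedule (two population iterations, two guided, two
pedigree-only) is orchestrated by :class:`HaplotypeImputer`, a scikit-learn
style transformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _kernels
from .ldsim import Density, GenotypeMatrix, MarkerMap, Pedigree

UNKNOWN = 1

__all__ = [
    "HaplotypeImputer",
    "HaplotypeLibrary",
    "ImputedGenotypes",
    "SegmentState",
    "segment_boundaries",
    "is_match",
    "complement",
    "run",
]

# provenance codes for called genotypes
OBSERVED, IMPUTED, HALF_FILLED, FREQUENCY_FILLED = 0, 1, 2, 3


def segment_boundaries(n_markers_on_chrom: int, segment_size: int) -> list[tuple[int, int]]:
    """Contiguous half-open marker ranges covering one chromosome.

    All segments have ``segment_size`` markers except the last, which keeps
    the remainder (a chromosome shorter than one segment yields a single
    shortened segment).
    """
    if n_markers_on_chrom <= 0 or segment_size <= 0:
        raise ValueError("marker count and segment size must be positive")
    bounds = []
    lo = 0
    while lo < n_markers_on_chrom:
        hi = min(lo + segment_size, n_markers_on_chrom)
        bounds.append((lo, hi))
        lo = hi
    return bounds


def is_match(genotype_segment, haplotype_entry) -> bool:
    """True iff no homozygous locus of the genotype conflicts with the entry."""
    g = np.asarray(genotype_segment, dtype=np.int8)
    h = np.asarray(haplotype_entry, dtype=np.int8)
    if g.shape != h.shape:
        raise ValueError("genotype and haplotype segments must have equal length")
    return bool(_kernels.conflicts_with(h, g) == 0)


def complement(genotype_segment, haplotype_entry, missing=None) -> np.ndarray:
    """Second haplotype obtained by subtracting the first from the genotype.

    Raises if the pair does not match.  ``missing`` marks truly missing
    genotype loci (default: none); without it an unknown code 1 is treated as
    an observed heterozygote.
    """
    g = np.asarray(genotype_segment, dtype=np.int8)
    h = np.asarray(haplotype_entry, dtype=np.int8)
    if not is_match(g, h):
        raise ValueError("complement() called on a non-matching genotype/haplotype pair")
    if missing is None:
        missing = np.zeros(g.shape, dtype=bool)
    return _kernels.complement_of(g, h, np.asarray(missing, dtype=bool))


@dataclass
class SegmentState:
    """Haplotype library and per-animal assignments for one segment."""

    chrom: int
    start: int
    stop: int
    lib: np.ndarray          # (cap, L) int8 entry alleles, 1 = unknown
    n_entries: int
    is_geno: np.ndarray      # bool, True while an entry is an unsplit genotype
    counts: np.ndarray       # int64 assignment counts
    hp: np.ndarray           # per animal: paternal-candidate entry index or -1
    hm: np.ndarray
    oriented: np.ndarray     # bool: parent-of-origin established by pedigree

    @property
    def length(self) -> int:
        return self.stop - self.start

    def entries(self) -> np.ndarray:
        return self.lib[: self.n_entries]

    def known_per_entry(self) -> np.ndarray:
        return (self.entries() != UNKNOWN).sum(axis=1)

    def resolved_alleles(self) -> np.ndarray:
        """Known-allele count of each animal's assigned pair."""
        k = np.concatenate([[0], self.known_per_entry()])
        return k[self.hp + 1] + k[self.hm + 1]

    def recount(self) -> None:
        c = np.zeros(self.n_entries, dtype=np.int64)
        for arr in (self.hp, self.hm):
            v = arr[arr >= 0]
            if v.size:
                c += np.bincount(v, minlength=self.n_entries)
        self.counts = c

    def resort(self) -> None:
        """Stable sort entries by frequency (desc), drop unreferenced ones."""
        self.recount()
        order = np.argsort(-self.counts[: self.n_entries], kind="stable")
        order = order[self.counts[order] > 0]
        remap = np.full(self.n_entries + 1, -1, dtype=np.int64)
        remap[order] = np.arange(order.size)
        n = order.size
        self.lib[:n] = self.lib[order]
        self.is_geno[:n] = self.is_geno[order]
        self.counts = self.counts[order]
        self.n_entries = n
        for arr in (self.hp, self.hm):
            pos = arr >= 0
            arr[pos] = remap[arr[pos]]
        self.hp = self.hp.astype(np.int32)
        self.hm = self.hm.astype(np.int32)

    def ensure_capacity(self, extra: int) -> None:
        need = self.n_entries + extra
        cap = self.lib.shape[0]
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        lib = np.full((new_cap, self.length), UNKNOWN, dtype=np.int8)
        lib[: self.n_entries] = self.entries()
        self.lib = lib
        ig = np.zeros(new_cap, dtype=bool)
        ig[: self.n_entries] = self.is_geno[: self.n_entries]
        self.is_geno = ig


@dataclass
class HaplotypeLibrary:
    """Frequency-ordered haplotype entries and animal assignments per segment."""

    segments: list[SegmentState] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_entries(self) -> int:
        return sum(s.n_entries for s in self.segments)


@dataclass
class ImputedGenotypes:
    """Called dosages with provenance, call rates and phased haplotypes."""

    dosage: np.ndarray       # float32 (animals x markers)
    provenance: np.ndarray   # int8: 0 observed, 1 imputed, 2 half, 3 freq-filled
    call_rate: np.ndarray    # float per animal
    hap_pat: np.ndarray      # int8 alleles {0,2}, 1 unknown
    hap_mat: np.ndarray
    oriented: np.ndarray     # bool (animals x segments)
    usable: np.ndarray       # non-genotyped animals whose call rate meets threshold


class HaplotypeImputer(BaseEstimator, TransformerMixin):
    """Impute missing genotypes by combined population/pedigree haplotyping.

    Parameters
    ----------
    pedigree
        :class:`~herd.ldsim.Pedigree` aligned with the genotype rows; when
        None, the pedigree-based iterations fall back to population passes.
    marker_map
        Marker map giving chromosome boundaries; when None all markers are
        treated as one chromosome.
    segment_size
        Markers per segment; None picks 500 for mixed-density input (animals
        with very different call fractions) and 100 otherwise.
    n_iterations
        Length of the schedule (default 6): population on the densest
        genotypes, population on all, two pedigree-guided, two pedigree-only.
    call_rate_threshold
        Minimum call rate for a non-genotyped ancestor's imputed genotype to
        be flagged usable.
    max_conflicts
        Parent/progeny conflicts tolerated (and corrected) per gamete fit in
        the pedigree-only iterations; more conflicts are flagged, not fixed.
    """

    def __init__(self, pedigree: Pedigree | None = None,
                 marker_map: MarkerMap | None = None,
                 segment_size: int | None = None, n_iterations: int = 6,
                 call_rate_threshold: float = 0.90, max_conflicts: int = 1,
                 check_invariants: bool = True):
        self.pedigree = pedigree
        self.marker_map = marker_map
        self.segment_size = segment_size
        self.n_iterations = n_iterations
        self.call_rate_threshold = call_rate_threshold
        self.max_conflicts = max_conflicts
        self.check_invariants = check_invariants

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        gm = self._as_matrix(X)
        self._G = gm.codes.copy()
        self._M = gm.missing.copy()
        n_animals, n_markers = self._G.shape
        ped = self.pedigree
        if ped is not None and ped.n_animals != n_animals:
            raise ValueError("pedigree and genotype matrix disagree on animal count")
        self._observed_per_row = (~self._M).sum(axis=1)
        self._genotyped = self._observed_per_row > 0
        if not np.any(self._genotyped):
            raise ValueError("no genotyped animals in input")
        if ped is not None:
            high = np.asarray(ped.density, dtype=np.int8) == int(Density.HIGH)
            self._high = high & self._genotyped
        else:
            self._high = self._genotyped.copy()
        if not np.any(self._high):
            self._high = self._genotyped.copy()
        seg_size = self.segment_size or self._auto_segment_size()
        self.segment_size_ = seg_size
        self._segments = self._init_segments(seg_size, n_animals, n_markers)
        self.allele_freq_ = self._estimate_freq()
        if ped is not None:
            self._order_all = np.asarray(
                [a for a in ped.topo_order if self._genotyped[a]], dtype=np.int64)
        else:
            self._order_all = np.flatnonzero(self._genotyped).astype(np.int64)
        self._order_high = np.asarray(
            [a for a in self._order_all if self._high[a]], dtype=np.int64)

        self.iteration_stats_ = []
        self.n_flagged_conflicts_ = 0
        self.n_corrected_ = 0
        self.n_crossovers_ = 0
        for it in range(self.n_iterations):
            phase = self._schedule(it)
            if phase == "population_high":
                self.population_pass(self._order_high, guided=False)
            elif phase == "population_all":
                self.population_pass(self._order_all, guided=False)
            elif phase == "guided":
                if ped is None:
                    self.population_pass(self._order_all, guided=False)
                else:
                    self.population_pass(self._order_all, guided=True)
            else:  # pedigree_only
                if ped is not None:
                    self.pedigree_pass()
            self._finish_iteration(it, phase)

        if ped is not None:
            self._final_orientation_pass()
        self.library_ = HaplotypeLibrary(self._segments)
        self.imputed_ = self.call_genotypes()
        return self

    def _final_orientation_pass(self) -> None:
        """Re-decide parent-of-origin with the fully refined library.

        Early orientation calls are made while parent haplotypes are still
        partially unknown; once the library has converged, comparing each
        animal's final pair against its parents' final pairs recovers
        orientations that were ambiguous at the time they were first set.
        Genotyped parents decide; assembled ancestors only break ties.
        """
        ped = self.pedigree
        for seg in self._segments:
            hp, hm = seg.hp, seg.hm
            for a in ped.topo_order:
                if not self._genotyped[a] or hp[a] < 0 or hm[a] < 0 or hp[a] == hm[a]:
                    continue

                def side_cost(entry, parent):
                    if parent < 0:
                        return None
                    ents = [e for e in (hp[parent], hm[parent]) if e >= 0]
                    if not ents:
                        return None
                    x = seg.lib[entry]
                    best = min(int(_kernels.conflicts_with(seg.lib[e], x)) for e in ents)
                    return best, bool(self._genotyped[parent])

                def orient_cost(p_entry, m_entry):
                    primary = secondary = 0
                    informative = False
                    for entry, parent in ((p_entry, ped.sire[a]), (m_entry, ped.dam[a])):
                        c = side_cost(entry, parent)
                        if c is None:
                            continue
                        informative = True
                        if c[1]:
                            primary += c[0]
                        else:
                            secondary += c[0]
                    return (primary, secondary) if informative else None

                keep = orient_cost(hp[a], hm[a])
                swap = orient_cost(hm[a], hp[a])
                if keep is None or swap is None:
                    continue
                if swap < keep:
                    hp[a], hm[a] = hm[a], hp[a]
                    seg.oriented[a] = True

    def transform(self, X=None):
        """Imputed dosage matrix for the fitted genotypes."""
        if not hasattr(self, "imputed_"):
            raise RuntimeError("HaplotypeImputer must be fitted before transform()")
        if X is not None:
            gm = self._as_matrix(X)
            if gm.codes.shape != self.imputed_.dosage.shape:
                raise ValueError("transform() only supports the matrix the imputer was fitted on")
        return self.imputed_.dosage

    # ---------------------------------------------------------------- setup
    def _as_matrix(self, X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        codes = np.asarray(X)
        missing = codes == 5
        codes = np.where(missing, 1, codes).astype(np.int8)
        return GenotypeMatrix(codes, missing)

    def _auto_segment_size(self) -> int:
        frac = self._observed_per_row[self._genotyped] / self._G.shape[1]
        mixed = frac.max() > 2.0 * max(frac.min(), 1e-9)
        return 500 if mixed else 100

    def _chrom_ranges(self, n_markers: int) -> list[tuple[int, int, int]]:
        if self.marker_map is None:
            return [(0, 0, n_markers)]
        starts, stops = self.marker_map.chrom_bounds()
        return [(c, int(lo), int(hi)) for c, (lo, hi) in enumerate(zip(starts, stops))]

    def _init_segments(self, seg_size: int, n_animals: int, n_markers: int) -> list[SegmentState]:
        segs = []
        for chrom, lo, hi in self._chrom_ranges(n_markers):
            for s_lo, s_hi in segment_boundaries(hi - lo, seg_size):
                L = s_hi - s_lo
                cap = 256
                segs.append(SegmentState(
                    chrom=chrom, start=lo + s_lo, stop=lo + s_hi,
                    lib=np.full((cap, L), UNKNOWN, dtype=np.int8),
                    n_entries=0,
                    is_geno=np.zeros(cap, dtype=bool),
                    counts=np.zeros(0, dtype=np.int64),
                    hp=np.full(n_animals, -1, dtype=np.int32),
                    hm=np.full(n_animals, -1, dtype=np.int32),
                    oriented=np.zeros(n_animals, dtype=bool),
                ))
        return segs

    def _estimate_freq(self) -> np.ndarray:
        obs = ~self._M
        n = obs.sum(axis=0)
        s = np.where(obs, self._G, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, s / (2.0 * n), 0.5)
        return np.clip(f, 1e-6, 1 - 1e-6)

    def _schedule(self, it: int) -> str:
        # first iteration: densest genotypes only; then everyone; then two
        # pedigree-guided and two pedigree-only iterations
        n = self.n_iterations
        if it == 0:
            return "population_high"
        if it == 1 or n <= 2:
            return "population_all"
        third = max(2, n - 4)
        if it < third + 2:
            return "guided"
        return "pedigree_only"

    # --------------------------------------------------------------- passes
    def population_pass(self, order: np.ndarray, guided: bool) -> None:
        """Scan the library for every animal in ``order``, segment by segment."""
        ped = self.pedigree
        sire = ped.sire if ped is not None else np.full(self._G.shape[0], -1, np.int32)
        dam = ped.dam if ped is not None else np.full(self._G.shape[0], -1, np.int32)
        for seg in self._segments:
            seg.ensure_capacity(2 * order.size + 4)
            G = np.ascontiguousarray(self._G[:, seg.start:seg.stop])
            M = np.ascontiguousarray(self._M[:, seg.start:seg.stop])
            seg.n_entries = _kernels.population_pass_segment(
                G, M, order, seg.lib, seg.is_geno, seg.n_entries,
                seg.hp, seg.hm, seg.oriented, guided, sire, dam)
            # mutual imputation may have refined entries; write homozygous
            # information back is library-only (genotypes are never edited here)

    def pedigree_pass(self) -> None:
        """Pedigree-only iteration: gamete refits and ancestor assembly."""
        ped = self.pedigree
        children_by_sire: dict[int, list[int]] = {}
        children_by_dam: dict[int, list[int]] = {}
        for a in range(ped.n_animals):
            if ped.sire[a] >= 0:
                children_by_sire.setdefault(int(ped.sire[a]), []).append(a)
            if ped.dam[a] >= 0:
                children_by_dam.setdefault(int(ped.dam[a]), []).append(a)
        for seg in self._segments:
            self._pedigree_pass_segment(seg, children_by_sire, children_by_dam)

    def _pedigree_pass_segment(self, seg: SegmentState,
                               children_by_sire, children_by_dam) -> None:
        ped = self.pedigree
        L = seg.length
        unknown_row = np.full(L, UNKNOWN, dtype=np.int8)
        seg.recount()

        def refit_sweep():
            for a in ped.topo_order:
                if not self._genotyped[a]:
                    continue
                g = self._G[a, seg.start:seg.stop]
                miss = self._M[a, seg.start:seg.stop]
                self._refit_animal(seg, a, g, miss, unknown_row)

        refit_sweep()
        # assemble non-genotyped ancestors from their oriented descendants
        for a in ped.topo_order[::-1]:
            if self._genotyped[a]:
                continue
            # oriented children vote (weight 2) with the gamete they received
            # from this parent; unoriented children vote once for each of
            # their two candidate haplotypes.  With several children the
            # parent's true pair collects the most votes.
            votes: dict[int, int] = {}
            n_voters = 0
            for side_children, side_arr in ((children_by_sire, seg.hp),
                                            (children_by_dam, seg.hm)):
                for child in side_children.get(int(a), []):
                    if seg.oriented[child]:
                        e = side_arr[child]
                        if e >= 0:
                            votes[int(e)] = votes.get(int(e), 0) + 2
                            n_voters += 1
                    elif seg.hp[child] >= 0 or seg.hm[child] >= 0:
                        n_voters += 1
                        for e in (seg.hp[child], seg.hm[child]):
                            if e >= 0:
                                votes[int(e)] = votes.get(int(e), 0) + 1
            if not votes or n_voters < 2:
                continue
            top = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            seg.hp[a] = top[0][0]
            seg.hm[a] = top[1][0] if len(top) > 1 else top[0][0]
            seg.oriented[a] = False
        # newly assembled ancestors let more progeny gametes be rebuilt
        # within the same iteration
        seg.recount()
        refit_sweep()

    def _parent_pair(self, seg: SegmentState, parent: int, unknown_row):
        """The parent's two haplotype rows, entry indices and phasing status."""
        if parent < 0:
            return None
        php, phm = seg.hp[parent], seg.hm[parent]
        if php < 0 and phm < 0:
            return None
        pA = seg.lib[php] if php >= 0 else unknown_row
        pB = seg.lib[phm] if phm >= 0 else pA
        # an assembled (non-genotyped) parent's pair is a vote-based guess,
        # not a phased genome: crossover stitching against it is not reliable
        phased = bool(self._genotyped[parent])
        return pA, pB, (php if php >= 0 else phm), (phm if phm >= 0 else php), phased

    def _refit_animal(self, seg: SegmentState, a: int, g: np.ndarray,
                      miss: np.ndarray, unknown_row: np.ndarray) -> None:
        """Rebuild the gametes of animal ``a`` from its parents' haplotypes.

        Each gamete is fitted as the parent's two haplotypes with at most one
        switch point (crossover), choosing the leftmost point with fewest
        homozygous conflicts.  When both parents are resolved, the
        parent-of-origin orientation of the current haplotype pair is chosen
        to minimize total conflicts over both gametes; a fit with at most
        ``max_conflicts`` conflicting markers is accepted, a single
        conflicting marker being treated as a genotyping error resolved in
        favour of the more frequent haplotype.
        """
        ped = self.pedigree
        sire_pair = self._parent_pair(seg, ped.sire[a], unknown_row)
        dam_pair = self._parent_pair(seg, ped.dam[a], unknown_row)
        if sire_pair is None and dam_pair is None:
            return
        cur = (int(seg.hp[a]), int(seg.hm[a]))
        orients = [(cur[0], cur[1])]
        if cur[1] != cur[0]:
            orients.append((cur[1], cur[0]))
        t_hard = self._gamete_target(g, miss, None)
        best = None
        for op, om in orients:
            # genotyped parents' phased pairs decide the orientation; the
            # vote-assembled pair of a non-genotyped ancestor only breaks ties
            primary = 0
            secondary = 0
            if sire_pair is not None:
                soft = self._soft_target(g, miss, seg.lib[om] if om >= 0 else None)
                _, ch, cs = self._best_switch(sire_pair[0], sire_pair[1], t_hard, soft,
                                              pure_only=not sire_pair[4])
                if sire_pair[4]:
                    primary += 1000 * ch + cs
                else:
                    secondary += 1000 * ch + cs
            if dam_pair is not None:
                soft = self._soft_target(g, miss, seg.lib[op] if op >= 0 else None)
                _, ch, cs = self._best_switch(dam_pair[0], dam_pair[1], t_hard, soft,
                                              pure_only=not dam_pair[4])
                if dam_pair[4]:
                    primary += 1000 * ch + cs
                else:
                    secondary += 1000 * ch + cs
            total = (primary, secondary)
            # ties keep the established orientation (the first listed pair)
            if best is None or total < best[0]:
                best = (total, op, om)
        _, op, om = best
        accepted = False
        if sire_pair is not None:
            new_p = self._fit_one_side(seg, a, g, miss, sire_pair, own_idx=op, other_idx=om)
            if new_p is not None:
                op = new_p
                accepted = True
        if dam_pair is not None:
            new_m = self._fit_one_side(seg, a, g, miss, dam_pair, own_idx=om, other_idx=op)
            if new_m is not None:
                om = new_m
                accepted = True
        if accepted:
            seg.hp[a] = op
            seg.hm[a] = om
            seg.oriented[a] = True

    def _fit_one_side(self, seg: SegmentState, a: int, g: np.ndarray, miss: np.ndarray,
                      parent_pair, own_idx: int, other_idx: int) -> int | None:
        """Fit one gamete against a parent's haplotype pair; None if rejected.

        Conflicts with the animal's own homozygous genotype are hard evidence
        (at most ``max_conflicts`` tolerated, resolved by the single-locus
        error rule); disagreements with phase *inferences* from the other
        haplotype are soft — the parent's allele wins there, since the other
        haplotype may itself be mis-phased.
        """
        pA, pB, entA, entB, phased = parent_pair
        other = seg.lib[other_idx] if other_idx >= 0 else None
        t_hard = self._gamete_target(g, miss, None)
        t_soft = self._soft_target(g, miss, other)
        k, hard, _ = self._best_switch(pA, pB, t_hard, t_soft, pure_only=not phased)
        # no conflict allowance against the vote-assembled pair of a
        # non-genotyped ancestor: a conflict there signals a wrong assembly,
        # not a genotyping error
        n_constraints = int(np.count_nonzero(t_hard != UNKNOWN))
        allowance = self.max_conflicts if phased else 0
        if hard > allowance:
            self.n_flagged_conflicts_ += 1
            return None
        L = t_hard.shape[0]
        hap = np.where(np.arange(L) < k, pA, pB).astype(np.int8)
        # an unresolved parent matches anything; only accept a fit that was
        # actually tested against most of the animal's homozygous loci
        covered = int(np.count_nonzero((t_hard != UNKNOWN) & (hap != UNKNOWN)))
        if n_constraints > 0 and covered < 0.8 * n_constraints:
            return None
        if 0 < k < L:
            self.n_crossovers_ += 1
        bad = (t_hard != UNKNOWN) & (hap != UNKNOWN) & (hap != t_hard)
        if np.any(bad):
            src = entA if k > 0 else entB
            parent_count = int(seg.counts[src]) if 0 <= src < len(seg.counts) else 0
            own_count = int(seg.counts[own_idx]) if 0 <= own_idx < len(seg.counts) else 0
            if phased and parent_count >= own_count:
                # genotyping error: parent haplotype wins, correct the genotype
                for l in np.flatnonzero(bad):
                    self._correct_genotype(a, seg, int(l), int(hap[l]), other_idx)
                self.n_corrected_ += 1
            else:
                hap[bad] = t_hard[bad]
        # fill remaining unknowns: own homozygous loci first, then phase
        # inferences where the parent carries no information
        fill = (hap == UNKNOWN) & (t_hard != UNKNOWN)
        hap[fill] = t_hard[fill]
        evidence = hap.copy()
        fill = (hap == UNKNOWN) & (t_soft != UNKNOWN)
        hap[fill] = t_soft[fill]
        return self._find_or_add(seg, hap, evidence)

    def _gamete_target(self, g, miss, other) -> np.ndarray:
        """Constraints on one gamete given the genotype and the other haplotype."""
        t = np.full(g.shape[0], UNKNOWN, dtype=np.int8)
        hom = g != UNKNOWN
        t[hom] = g[hom]
        if other is not None:
            het = (g == UNKNOWN) & ~miss & (other != UNKNOWN)
            t[het] = 2 - other[het]
        return t

    @staticmethod
    def _soft_target(g, miss, other) -> np.ndarray:
        """Phase inferences only: alleles implied at observed heterozygotes."""
        t = np.full(g.shape[0], UNKNOWN, dtype=np.int8)
        if other is not None:
            het = (g == UNKNOWN) & ~miss & (other != UNKNOWN)
            t[het] = 2 - other[het]
        return t

    @staticmethod
    def _best_switch(pA, pB, t_hard, t_soft=None, pure_only=False) -> tuple[int, int, int]:
        """Leftmost switch point A[:k]+B[k:] minimizing conflicts.

        Hard conflicts (own homozygous genotype) dominate; soft conflicts
        (phase inferences) break ties.  With ``pure_only`` only the two
        unrecombined choices (k = 0 or k = L) are considered.  Returns
        (k, hard, soft).
        """
        def cum(t, p):
            conf = (t != UNKNOWN) & (p != UNKNOWN) & (p != t)
            return np.concatenate([[0], np.cumsum(conf)])

        hA, hB = cum(t_hard, pA), cum(t_hard, pB)
        hard = hA + (hB[-1] - hB)
        if t_soft is not None:
            sA, sB = cum(t_soft, pA), cum(t_soft, pB)
            soft = sA + (sB[-1] - sB)
        else:
            soft = np.zeros_like(hard)
        cost = 1000 * hard + soft
        if pure_only:
            L = len(cost) - 1
            k = 0 if cost[0] <= cost[L] else L
        else:
            k = int(np.argmin(cost))
        return k, int(hard[k]), int(soft[k])

    def _correct_genotype(self, a: int, seg: SegmentState, l: int,
                          hap_allele: int, other_idx: int) -> None:
        """Apply the single-locus conflict rule: overwrite the stored genotype."""
        marker = seg.start + l
        other = int(seg.lib[other_idx, l]) if other_idx >= 0 else UNKNOWN
        if other != UNKNOWN and hap_allele != UNKNOWN:
            self._G[a, marker] = np.int8((hap_allele + other) // 2)
            self._M[a, marker] = False
        else:
            self._G[a, marker] = UNKNOWN
            self._M[a, marker] = True

    def _find_or_add(self, seg: SegmentState, hap: np.ndarray,
                     evidence: np.ndarray | None = None) -> int:
        """Store a haplotype, reusing a compatible near-identical entry.

        When a shared entry is reused, only ``evidence`` alleles (genotype- or
        parent-supported) are merged into it; single-animal phase inferences
        stay out of shared entries.
        """
        tol = max(3, int(0.05 * seg.length))
        i = _kernels.dedup_match(seg.lib, seg.n_entries, hap, tol)
        if i >= 0:
            _kernels.merge_into(seg.lib, i, hap if evidence is None else evidence)
            return i
        seg.ensure_capacity(1)
        i = seg.n_entries
        seg.lib[i] = hap
        seg.is_geno[i] = False
        seg.n_entries += 1
        if len(seg.counts) < seg.n_entries:
            seg.counts = np.concatenate([seg.counts, np.zeros(seg.n_entries - len(seg.counts), np.int64)])
        return i

    # ------------------------------------------------------- pass bookkeeping
    def _finish_iteration(self, it: int, phase: str) -> None:
        total_resolved = 0
        prev = getattr(self, "_prev", None)
        for si, seg in enumerate(self._segments):
            new_res = seg.resolved_alleles()
            if prev is not None:
                old_hp, old_hm, old_or = prev[si]
                old_now = self._resolved_of(seg, old_hp, old_hm)
                worse = (new_res < old_now) & (old_hp >= 0)
                if np.any(worse):
                    # genotype corrections may have invalidated old pairs;
                    # only restore pairs still consistent with the genotypes
                    G = self._G[:, seg.start:seg.stop]
                    rows = np.flatnonzero(worse)
                    for arr in (old_hp, old_hm):
                        H = seg.lib[arr[rows]]
                        ok = ~((G[rows] != UNKNOWN) & (H != UNKNOWN)
                               & (G[rows] != H)).any(axis=1)
                        rows = rows[ok]
                    seg.hp[rows] = old_hp[rows]
                    seg.hm[rows] = old_hm[rows]
                    seg.oriented[rows] = old_or[rows]
                    new_res = seg.resolved_alleles()
            seg.resort()
            if self.check_invariants:
                self._assert_consistent(seg)
            total_resolved += int(new_res.sum())
        self._prev = [(seg.hp.copy(), seg.hm.copy(), seg.oriented.copy())
                      for seg in self._segments]
        n_animals, n_markers = self._G.shape
        unknown_fraction = 1.0 - total_resolved / (2.0 * n_animals * n_markers)
        self.iteration_stats_.append({
            "iteration": it + 1,
            "phase": phase,
            "library_entries": sum(s.n_entries for s in self._segments),
            "unknown_allele_fraction": unknown_fraction,
        })

    @staticmethod
    def _resolved_of(seg: SegmentState, hp, hm) -> np.ndarray:
        k = np.concatenate([[0], seg.known_per_entry()])
        return k[hp + 1] + k[hm + 1]

    def _assert_consistent(self, seg: SegmentState) -> None:
        """No assigned haplotype may conflict with an observed homozygous locus."""
        G = self._G[:, seg.start:seg.stop]
        for arr in (seg.hp, seg.hm):
            rows = np.flatnonzero(arr >= 0)
            if rows.size == 0:
                continue
            H = seg.lib[arr[rows]]
            bad = (G[rows] != UNKNOWN) & (H != UNKNOWN) & (G[rows] != H)
            if np.any(bad):
                raise RuntimeError(
                    f"library inconsistency in segment {seg.chrom}:{seg.start}-{seg.stop}")

    # ----------------------------------------------------------------- calls
    def call_genotypes(self) -> ImputedGenotypes:
        """Final dosages: observed, imputed, half- or frequency-filled."""
        n_animals, n_markers = self._G.shape
        hap_pat = np.full((n_animals, n_markers), UNKNOWN, dtype=np.int8)
        hap_mat = np.full((n_animals, n_markers), UNKNOWN, dtype=np.int8)
        oriented = np.zeros((n_animals, len(self._segments)), dtype=bool)
        for si, seg in enumerate(self._segments):
            lib_ext = np.vstack([seg.entries(),
                                 np.full((1, seg.length), UNKNOWN, np.int8)])
            hap_pat[:, seg.start:seg.stop] = lib_ext[seg.hp]
            hap_mat[:, seg.start:seg.stop] = lib_ext[seg.hm]
            oriented[:, si] = seg.oriented
        freq = self.allele_freq_
        pk = hap_pat != UNKNOWN
        mk = hap_mat != UNKNOWN
        both = pk & mk
        one = pk ^ mk
        dosage = np.where(both, (hap_pat + hap_mat) / 2.0, 2.0 * freq[None, :])
        single = np.where(pk, hap_pat, hap_mat) / 2.0 + freq[None, :]
        dosage = np.where(one, single, dosage).astype(np.float32)
        observed = ~self._M
        dosage[observed] = self._G[observed]
        provenance = np.full(dosage.shape, FREQUENCY_FILLED, dtype=np.int8)
        provenance[one] = HALF_FILLED
        provenance[both] = IMPUTED
        provenance[observed] = OBSERVED
        determined = np.where(observed | both, 1.0, np.where(one, 0.5, 0.0))
        call_rate = determined.mean(axis=1)
        usable = (~self._genotyped) & (call_rate >= self.call_rate_threshold)
        return ImputedGenotypes(dosage=dosage, provenance=provenance,
                                call_rate=call_rate, hap_pat=hap_pat,
                                hap_mat=hap_mat, oriented=oriented, usable=usable)


def run(genotypes, pedigree: Pedigree | None = None,
        marker_map: MarkerMap | None = None, segment_size: int | None = None,
        n_iterations: int = 6, call_rate_threshold: float = 0.90,
        ) -> tuple[HaplotypeLibrary, ImputedGenotypes]:
    """Run the full haplotyping schedule; functional wrapper around the imputer."""
    imp = HaplotypeImputer(pedigree=pedigree, marker_map=marker_map,
                           segment_size=segment_size, n_iterations=n_iterations,
                           call_rate_threshold=call_rate_threshold)
    imp.fit(genotypes)
    return imp.library_, imp.imputed_
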