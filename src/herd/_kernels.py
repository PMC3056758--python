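"""Numba kernels for the segment-library matcher and the iterative solver.

Codes follow the package convention: genotypes 0/2 homozygous, 1
heterozygous-or-unknown; haplotype alleles 0/2 known, 1 unknown.  A genotype
and a stored haplotype (or genotype-entry) *conflict* only where both carry a
code other than 1 and the codes differ — this single rule drives all
matching.
"""

from __future__ import annotations

import numpy as np
from numba import njit

UNKNOWN = 1


@njit(cache=True)
def first_match(lib, n_entries, x, start):
    """Index of the first stored entry not conflicting with ``x``; -1 if none."""
    L = x.shape[0]
    for i in range(start, n_entries):
        ok = True
        for l in range(L):
            xl = x[l]
            hl = lib[i, l]
            if xl != UNKNOWN and hl != UNKNOWN and xl != hl:
                ok = False
                break
        if ok:
            return i
    return -1


@njit(cache=True)
def conflicts_with(entry, x):
    """Number of loci where ``entry`` and ``x`` are both known and differ."""
    c = 0
    for l in range(x.shape[0]):
        if x[l] != UNKNOWN and entry[l] != UNKNOWN and x[l] != entry[l]:
            c += 1
    return c


@njit(cache=True)
def merge_into(lib, i, x):
    """Fill unknown alleles of entry ``i`` from the known codes of ``x``.

    For a haplotype entry this is the mutual-imputation step; for a stored
    genotype-entry it is the split: loci homozygous in either record become
    known, loci heterozygous/unknown in both stay unknown.
    """
    for l in range(x.shape[0]):
        if lib[i, l] == UNKNOWN and x[l] != UNKNOWN:
            lib[i, l] = x[l]


@njit(cache=True)
def complement_of(g, h, missing):
    """Second haplotype implied by genotype ``g`` given first haplotype ``h``.

    Homozygous genotype forces the complement allele; an observed
    heterozygote with a known haplotype allele forces the opposite allele;
    a truly missing genotype, or an unknown haplotype allele under a
    heterozygote, yields unknown.
    """
    L = g.shape[0]
    c = np.empty(L, dtype=np.int8)
    for l in range(L):
        if g[l] != UNKNOWN:
            c[l] = g[l]
        elif missing[l] or h[l] == UNKNOWN:
            c[l] = UNKNOWN
        else:
            c[l] = 2 - h[l]
    return c


@njit(cache=True)
def _gather_candidates(a, sire, dam, hp, hm, out):
    """Parent (else grandparent) entry indices to try first: sire side then dam.

    Returns (n_sire_side, n_total).  Unresolved parents fall back to their own
    parents' entries.
    """
    n = 0
    n_sire = 0
    for side in range(2):
        parent = sire[a] if side == 0 else dam[a]
        if parent >= 0:
            if hp[parent] >= 0 or hm[parent] >= 0:
                if hp[parent] >= 0:
                    out[n] = hp[parent]
                    n += 1
                if hm[parent] >= 0 and hm[parent] != hp[parent]:
                    out[n] = hm[parent]
                    n += 1
            else:
                for gp in (sire[parent], dam[parent]):
                    if gp >= 0:
                        if hp[gp] >= 0:
                            out[n] = hp[gp]
                            n += 1
                        if hm[gp] >= 0 and hm[gp] != hp[gp]:
                            out[n] = hm[gp]
                            n += 1
        if side == 0:
            n_sire = n
    return n_sire, n


@njit(cache=True)
def population_pass_segment(G, M, order, lib, is_geno, n_entries,
                            hp, hm, oriented, use_ped, sire, dam):
    """One pass of population (optionally pedigree-guided) haplotyping.

    ``G``/``M`` are the genotype codes and missing mask restricted to one
    segment; ``lib`` a preallocated entry array; ``hp``/``hm`` the per-animal
    paternal-/maternal-candidate entry indices.  Animals are processed in
    ``order``.  With ``use_ped``, known parent (or grandparent) haplotype
    indices are tried before any sequential list scan and determine the
    parent-of-origin orientation.  Returns the new number of entries.
    """
    cap = lib.shape[0]
    cand = np.empty(8, dtype=np.int64)
    for oi in range(order.shape[0]):
        a = order[oi]
        g = G[a]
        i1 = -1
        from_sire = False
        from_dam = False
        n_sire = 0
        n_cand = 0
        if use_ped:
            n_sire, n_cand = _gather_candidates(a, sire, dam, hp, hm, cand)
            # strongest evidence first: a sire candidate matching the genotype
            # whose complement matches a dam candidate (and vice versa)
            pair_p = -1
            pair_m = -1
            pair_first = -1  # the entry that matched the genotype itself
            for si in range(n_sire):
                e = cand[si]
                if e < 0 or e >= n_entries or conflicts_with(lib[e], g) != 0:
                    continue
                c = complement_of(g, lib[e], M[a])
                for dj in range(n_sire, n_cand):
                    f = cand[dj]
                    if f < 0 or f >= n_entries:
                        continue
                    if conflicts_with(lib[f], c) == 0:
                        pair_p = e
                        pair_m = f
                        pair_first = e
                        break
                if pair_p >= 0:
                    break
            if pair_p < 0:
                for dj in range(n_sire, n_cand):
                    f = cand[dj]
                    if f < 0 or f >= n_entries or conflicts_with(lib[f], g) != 0:
                        continue
                    c = complement_of(g, lib[f], M[a])
                    for si in range(n_sire):
                        e = cand[si]
                        if e < 0 or e >= n_entries:
                            continue
                        if conflicts_with(lib[e], c) == 0:
                            pair_p = e
                            pair_m = f
                            pair_first = f
                            break
                    if pair_m >= 0:
                        break
            if pair_p >= 0:
                second = pair_m if pair_first == pair_p else pair_p
                # mutual imputation uses homozygous information only (the
                # genotype's known codes); phase inferences are never written
                # back into the library, so one false match cannot corrupt a
                # frequent entry
                merge_into(lib, pair_first, g)
                is_geno[pair_first] = False
                merge_into(lib, second, g)
                is_geno[second] = False
                hp[a] = pair_p
                hm[a] = pair_m
                oriented[a] = True
                continue
            for ci in range(n_cand):
                e = cand[ci]
                if e < 0 or e >= n_entries:
                    continue
                if conflicts_with(lib[e], g) == 0:
                    i1 = e
                    from_sire = ci < n_sire
                    from_dam = not from_sire
                    break
        if i1 < 0:
            i1 = first_match(lib, n_entries, g, 0)
            from_sire = False
            from_dam = False
        if i1 < 0:
            if n_entries < cap:
                lib[n_entries] = g
                is_geno[n_entries] = True
                hp[a] = n_entries
                hm[a] = n_entries
                oriented[a] = False
                n_entries += 1
            continue
        merge_into(lib, i1, g)
        is_geno[i1] = False
        c = complement_of(g, lib[i1], M[a])
        i2 = -1
        if use_ped and n_cand > 0:
            # try the other parent's candidates for the complement first
            lo = n_sire if from_sire else 0
            hi = n_cand if from_sire else n_sire
            for ci in range(lo, hi):
                e = cand[ci]
                if e < 0 or e >= n_entries:
                    continue
                if conflicts_with(lib[e], c) == 0:
                    i2 = e
                    break
        if i2 < 0:
            start = 0 if use_ped else i1
            i2 = first_match(lib, n_entries, c, start)
        if i2 < 0:
            if n_entries < cap:
                lib[n_entries] = c
                is_geno[n_entries] = False
                i2 = n_entries
                n_entries += 1
            else:
                i2 = i1
        else:
            # fill from homozygous loci only: c's phase inferences at
            # heterozygous loci are this animal's hypothesis, not evidence
            merge_into(lib, i2, g)
            is_geno[i2] = False
        if from_dam:
            hp[a] = i2
            hm[a] = i1
            oriented[a] = True
        else:
            hp[a] = i1
            hm[a] = i2
            oriented[a] = from_sire
    return n_entries


@njit(cache=True)
def dedup_match(lib, n_entries, hap, tol):
    """Storage dedup: first entry with no conflict and near-identical coverage.

    ``tol`` bounds the number of loci known in exactly one of the two
    records; larger divergence forces a fresh entry so that a mostly-unknown
    entry cannot swallow a well-resolved haplotype.
    """
    L = hap.shape[0]
    for i in range(n_entries):
        ok = True
        one_sided = 0
        for l in range(L):
            e = lib[i, l]
            h = hap[l]
            if h != UNKNOWN and e != UNKNOWN:
                if h != e:
                    ok = False
                    break
            elif h != e:
                one_sided += 1
                if one_sided > tol:
                    ok = False
                    break
        if ok:
            return i
    return -1


@njit(cache=True)
def gs_marker_sweep(Z, rinv, e, u, lam, zRz):
    """One Gauss–Seidel sweep over marker effects with residual updating."""
    n, m = Z.shape
    for j in range(m):
        num = 0.0
        for i in range(n):
            num += Z[i, j] * rinv[i] * e[i]
        num += zRz[j] * u[j]
        new = num / (zRz[j] + lam[j])
        d = new - u[j]
        if d != 0.0:
            for i in range(n):
                e[i] -= Z[i, j] * d
        u[j] = new


@njit(cache=True)
def gs_poly_sweep(indptr, indices, data, p, rec_row, rinv, e, lam_p):
    """One Gauss–Seidel sweep over polygenic effects.

    ``indptr``/``indices``/``data`` hold the CSR pedigree-relationship
    inverse; ``rec_row[i]`` is the record index of animal ``i`` (-1 if the
    animal has no record).
    """
    n = p.shape[0]
    for i in range(n):
        diag = 0.0
        off = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            if j == i:
                diag = data[k]
            else:
                off += data[k] * p[j]
        r = rec_row[i]
        wrw = rinv[r] if r >= 0 else 0.0
        rhs = -lam_p * off
        if r >= 0:
            rhs += rinv[r] * (e[r] + p[i])
        denom = wrw + lam_p * diag
        new = rhs / denom
        d = new - p[i]
        if r >= 0 and d != 0.0:
            e[r] -= d
        p[i] = new
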