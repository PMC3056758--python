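"""Independent brute-force oracles for small problem instances."""

import itertools

import numpy as np


def enumerate_splits(g):
    """All unordered phase splits (h1, h2) with h1 + h2 = 2 * g codes.

    ``g`` uses codes 0/1/2; haplotype alleles are 0/2.  The first
    heterozygous locus is fixed to break the pair symmetry.
    """
    g = np.asarray(g, dtype=np.int8)
    het = np.flatnonzero(g == 1)
    base = np.where(g == 2, 2, 0).astype(np.int8)
    if het.size == 0:
        yield base, base.copy()
        return
    first = het[0]
    for bits in itertools.product((0, 2), repeat=het.size - 1):
        h1 = base.copy()
        h2 = base.copy()
        h1[first] = 2
        h2[first] = 0
        for locus, b in zip(het[1:], bits):
            h1[locus] = b
            h2[locus] = 2 - b
        yield h1, h2


def parsimony_phasing_min(G) -> int:
    """Minimum number of distinct haplotypes over all exact phasings.

    Exhaustive depth-first search with branch-and-bound; feasible for about
    a dozen animals over at most 8 markers.
    """
    G = [np.asarray(g, dtype=np.int8) for g in G]
    order = sorted(range(len(G)), key=lambda i: int(np.sum(G[i] == 1)))
    best = [2 * len(G) + 1]

    def dfs(i, used):
        if len(used) >= best[0]:
            return
        if i == len(order):
            best[0] = len(used)
            return
        options = []
        for h1, h2 in enumerate_splits(G[order[i]]):
            k1, k2 = h1.tobytes(), h2.tobytes()
            new = {k for k in (k1, k2) if k not in used}
            options.append(new)
        options.sort(key=len)
        for new in options:
            used |= new
            dfs(i + 1, used)
            used -= new

    dfs(0, set())
    return best[0]


def dense_mme_solve(y, Z, rinv, lam, a_inverse=None, rec_animal=None, lam_p=0.0):
    """Direct dense solve of the mixed-model equations.

    Unknowns are [b, u, (p)] with a flat prior on b, common (or per-marker)
    ridge ``lam`` on u, and lam_p * A^-1 on p.  Returns (b, u, p).
    """
    n, m = Z.shape
    X = np.ones((n, 1))
    blocks = [X, Z]
    n_p = 0
    if a_inverse is not None:
        n_p = a_inverse.shape[0]
        W = np.zeros((n, n_p))
        W[np.arange(n), rec_animal] = 1.0
        blocks.append(W)
    Wall = np.hstack(blocks)
    R = np.diag(rinv)
    lhs = Wall.T @ R @ Wall
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (m,))
    lhs[1:1 + m, 1:1 + m] += np.diag(lam)
    if n_p:
        dense_a = np.asarray(a_inverse.todense())
        lhs[1 + m:, 1 + m:] += lam_p * dense_a
    rhs = Wall.T @ R @ y
    sol = np.linalg.solve(lhs, rhs)
    b = sol[0]
    u = sol[1:1 + m]
    p = sol[1 + m:] if n_p else None
    return b, u, p
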