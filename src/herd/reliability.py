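"""Daughter-equivalent machinery for approximate genomic reliabilities.

A reliability r converts to daughter equivalents DE = k r / (1 - r), with k
the ratio of error to sire variance; daughter equivalents from independent
information sources add, and the sum maps back through r = DE / (DE + k).
The genomic information of a reference population is summarized as

    DE_max = sum(REL_trad - REL_pa) * k / n

with n the equivalent reference size needed for 50% genomic reliability.
The ceiling on genomic reliability is REL_max = (1 - poly) DE_max/(DE_max+k)
— poly being the fraction of additive variance the marker panel cannot
trace — and an individual's genomic daughter equivalents, discounted by its
imputation quality REL_snp (squared correlation of estimated and true
genotypes), are

    DE_gen = k REL_max REL_snp / (1 - REL_max REL_snp)

so its published total is REL_tot = (DE_trad + DE_gen)/(DE_trad + DE_gen + k).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "de_from_rel",
    "rel_from_de",
    "de_max_total",
    "rel_max",
    "de_gen",
    "rel_tot",
    "solve_poly",
    "equivalent_n",
    "project_reliability",
]

#: worked default for the error-to-sire variance ratio
DEFAULT_K = 15.0
#: solved polygenic fractions by marker density (panel size -> poly)
DEFAULT_POLY = {3_000: 0.30, 50_000: 0.034, 500_000: 0.01}


def de_from_rel(rel, k: float = DEFAULT_K):
    """Daughter equivalents k*rel/(1-rel); rejects rel outside [0, 1)."""
    rel = np.asarray(rel, dtype=float)
    if np.any((rel < 0) | (rel >= 1)):
        raise ValueError("reliability must lie in [0, 1)")
    if k <= 0:
        raise ValueError("k must be positive")
    out = k * rel / (1.0 - rel)
    return float(out) if out.ndim == 0 else out


def rel_from_de(de, k: float = DEFAULT_K):
    """Reliability de/(de+k); exact inverse of :func:`de_from_rel`."""
    de = np.asarray(de, dtype=float)
    if np.any(de < 0):
        raise ValueError("daughter equivalents must be non-negative")
    out = de / (de + k)
    return float(out) if out.ndim == 0 else out


def de_max_total(rel_trad, rel_pa, k: float = DEFAULT_K, n: float = 1.0) -> float:
    """Total genomic daughter equivalents of a reference population.

    sum(REL_trad - REL_pa) * k / n.  Negative summands (an animal whose
    parent average outranks its own proof) are tolerated with a warning; the
    total must remain non-negative.
    """
    rel_trad = np.asarray(rel_trad, dtype=float)
    rel_pa = np.asarray(rel_pa, dtype=float)
    if rel_trad.shape != rel_pa.shape:
        raise ValueError("rel_trad and rel_pa must be aligned")
    if n <= 0:
        raise ValueError("equivalent reference size n must be positive")
    diff = rel_trad - rel_pa
    if np.any(diff < 0):
        warnings.warn("some REL_trad below REL_pa; their contribution is negative",
                      stacklevel=2)
    total = float(diff.sum()) * k / n
    if total < 0:
        raise ValueError("total daughter equivalents must be non-negative")
    return total


def rel_max(poly: float, de_max: float, k: float = DEFAULT_K) -> float:
    """Ceiling (1 - poly) * DE_max / (DE_max + k) on genomic reliability."""
    if not 0.0 <= poly < 1.0:
        raise ValueError("poly must lie in [0, 1)")
    if de_max < 0:
        raise ValueError("DE_max must be non-negative")
    return (1.0 - poly) * de_max / (de_max + k)


def de_gen(k: float, rel_max_: float, rel_snp: float) -> float:
    """Genomic daughter equivalents discounted by imputation quality.

    k * REL_max * REL_snp / (1 - REL_max * REL_snp); the product must stay
    below 1.
    """
    prod = rel_max_ * rel_snp
    if prod >= 1.0:
        raise ValueError("REL_max * REL_snp must be below 1")
    if prod < 0:
        raise ValueError("REL_max and REL_snp must be non-negative")
    return k * prod / (1.0 - prod)


def rel_tot(de_trad: float, de_gen_: float, k: float = DEFAULT_K) -> float:
    """Total reliability from summed daughter equivalents."""
    if de_trad < 0 or de_gen_ < 0:
        raise ValueError("daughter equivalents must be non-negative")
    return rel_from_de(de_trad + de_gen_, k)


def solve_poly(rel_max_low: float, rel_max_high: float, poly_high: float) -> float:
    """Polygenic fraction at a lower marker density.

    Equating DE_max across densities gives
    poly_low = 1 - (1 - poly_high) * rel_max_low / rel_max_high.
    """
    if not (0 < rel_max_low <= rel_max_high < 1):
        raise ValueError("need 0 < rel_max_low <= rel_max_high < 1")
    return 1.0 - (1.0 - poly_high) * rel_max_low / rel_max_high


def equivalent_n(sum_de_diff: float, k: float, de_max: float) -> float:
    """Equivalent reference size n = sum(REL_trad - REL_pa) * k / DE_max."""
    if de_max <= 0:
        raise ValueError("DE_max must be positive")
    return sum_de_diff * k / de_max


def project_reliability(n_reference: int, mean_rel_diff: float, k: float,
                        n: float, poly: float, rel_snp: float = 1.0,
                        de_trad: float = 0.0) -> float:
    """Expected REL_tot for a hypothetical reference population.

    Composes DE_max -> REL_max -> DE_gen -> REL_tot with a deliberately
    simple chain (no parent-average daughter equivalents added back); it
    projects trends over reference size and density, not any particular
    published curve.
    """
    de_max = n_reference * mean_rel_diff * k / n
    rm = rel_max(poly, de_max, k)
    dg = de_gen(k, rm, rel_snp)
    return rel_tot(de_trad, dg, k)
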