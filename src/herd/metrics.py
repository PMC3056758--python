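"""Imputation-success, haplotype-library and LD statistics.

All comparisons are against simulation truth (true genotypes and phased
haplotypes), which is the point of simulating: genotype and phase accuracy
cannot be measured on real data.  Results are split by age group — "old"
animals have a phenotype record in the reference population, "young" animals
do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotyper import (FREQUENCY_FILLED, HALF_FILLED, IMPUTED, OBSERVED,
                         HaplotypeLibrary, ImputedGenotypes)

UNKNOWN = 1

__all__ = [
    "ImputationReport",
    "HaplotypeStats",
    "imputation_report",
    "phase_error_rate",
    "paternal_origin_error_rate",
    "rel_snp",
    "haplotype_stats",
    "ld_r2_by_distance",
]


@dataclass
class ImputationReport:
    """Per-group imputation success measures, percentages in [0, 100]."""

    group: str
    n_animals: int
    pct_missing_before: float
    pct_missing_after: float
    genotype_error_rate: float       # half-error variant, imputed+assigned loci
    pct_incorrect_genotypes: float   # full count, all loci
    pct_incorrect_phase: float
    pct_incorrect_paternal: float
    mean_rel_snp: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


@dataclass
class HaplotypeStats:
    mean_haplotypes_per_segment: float
    sd_haplotypes_per_segment: float
    most_frequent_share: float       # share of all assignments, in (0, 1]
    mean_observations_per_haplotype: float


def _group_masks(old_mask: np.ndarray, scored: np.ndarray) -> dict[str, np.ndarray]:
    old = np.asarray(old_mask, dtype=bool) & scored
    young = ~np.asarray(old_mask, dtype=bool) & scored
    return {"young": young, "old": old, "all": scored}


def imputation_report(imputed: ImputedGenotypes, truth_dosage: np.ndarray,
                      truth_haplotypes: np.ndarray, old_mask: np.ndarray,
                      missing_before: np.ndarray,
                      scored: np.ndarray | None = None) -> pd.DataFrame:
    """Success measures for each age group (young / old / all).

    ``missing_before`` marks entries missing in the input (before
    imputation); ``scored`` selects the animals evaluated (default: animals
    with at least one observed genotype).  Incorrect genotypes are counted
    over all loci (observed, imputed, and frequency-assigned — the latter
    rounded to the nearest code), while the half-error rate covers only the
    imputed and assigned loci, scoring het-vs-hom differences as half an
    error and opposite homozygotes as a full error.
    """
    truth_dosage = np.asarray(truth_dosage)
    if scored is None:
        scored = (imputed.provenance == OBSERVED).any(axis=1)
    rows = []
    prov = imputed.provenance
    est_round = np.rint(imputed.dosage).astype(np.int8)
    for name, gmask in _group_masks(old_mask, scored).items():
        if gmask.sum() == 0:
            continue
        sub = np.flatnonzero(gmask)
        p = prov[sub]
        before = missing_before[sub]
        est = est_round[sub]
        tru = truth_dosage[sub]
        n_entries = p.size
        pct_before = 100.0 * before.mean()
        # not (fully) determined after imputation: frequency filled counts 1,
        # half filled counts one half
        after = (p == FREQUENCY_FILLED) + 0.5 * (p == HALF_FILLED)
        pct_after = 100.0 * after.mean()
        wrong = est != tru
        pct_incorrect = 100.0 * wrong.mean()
        filled = p != OBSERVED
        if filled.sum():
            diff = np.abs(est[filled] - tru[filled])
            half_err = np.where(diff == 2, 1.0, np.where(diff == 1, 0.5, 0.0))
            err_rate = 100.0 * half_err.mean()
        else:
            err_rate = 0.0
        phase = phase_error_rate(imputed.hap_pat[sub], imputed.hap_mat[sub],
                                 truth_haplotypes[sub])
        paternal = paternal_origin_error_rate(
            imputed.hap_pat[sub], imputed.hap_mat[sub], truth_haplotypes[sub])
        rsnp = rel_snp(imputed.dosage[sub], tru)
        rows.append(ImputationReport(
            group=name, n_animals=len(sub),
            pct_missing_before=pct_before, pct_missing_after=pct_after,
            genotype_error_rate=err_rate, pct_incorrect_genotypes=pct_incorrect,
            pct_incorrect_phase=phase, pct_incorrect_paternal=paternal,
            mean_rel_snp=float(np.nanmean(rsnp))).to_series())
    return pd.DataFrame(rows).set_index("group")


def phase_error_rate(hap_pat: np.ndarray, hap_mat: np.ndarray,
                     truth_haplotypes: np.ndarray) -> float:
    """Percentage of consecutive-heterozygote linkages called incorrectly.

    For every animal, consecutive marker pairs that are heterozygous (in
    truth) and phased in the estimate are compared: the linkage is the
    indicator that the paternal alleles at the two loci are equal, and an
    error is a disagreement between estimated and true linkage.  Animals
    with fewer than two usable heterozygous loci contribute no pairs.
    """
    hp = np.asarray(hap_pat)
    hm = np.asarray(hap_mat)
    n_pairs = 0
    n_err = 0
    for a in range(hp.shape[0]):
        t_het = truth_haplotypes[a, 0] != truth_haplotypes[a, 1]
        usable = t_het & (hp[a] != UNKNOWN) & (hm[a] != UNKNOWN) & (hp[a] != hm[a])
        idx = np.flatnonzero(usable)
        if idx.size < 2:
            continue
        est_link = hp[a, idx[:-1]] == hp[a, idx[1:]]
        true_link = truth_haplotypes[a, 0, idx[:-1]] == truth_haplotypes[a, 0, idx[1:]]
        n_pairs += idx.size - 1
        n_err += int(np.count_nonzero(est_link != true_link))
    return 100.0 * n_err / n_pairs if n_pairs else 0.0


def paternal_origin_error_rate(hap_pat: np.ndarray, hap_mat: np.ndarray,
                               truth_haplotypes: np.ndarray) -> float:
    """Percentage of heterozygous loci whose paternal label is wrong.

    Scored at loci heterozygous in truth where both estimated alleles are
    determined and heterozygous (both true and estimated phases exist).
    """
    hp = np.asarray(hap_pat)
    hm = np.asarray(hap_mat)
    t_het = truth_haplotypes[:, 0] != truth_haplotypes[:, 1]
    scored = t_het & (hp != UNKNOWN) & (hm != UNKNOWN) & (hp != hm)
    if not scored.any():
        return 0.0
    wrong = hp[scored] != truth_haplotypes[:, 0][scored]
    return 100.0 * wrong.mean()


def rel_snp(estimated_dosage: np.ndarray, true_dosage: np.ndarray) -> np.ndarray:
    """Squared correlation of estimated vs true dosages across loci, per animal.

    Defined as 0 when either vector is constant (no information).
    """
    est = np.asarray(estimated_dosage, dtype=np.float64)
    tru = np.asarray(true_dosage, dtype=np.float64)
    est_c = est - est.mean(axis=1, keepdims=True)
    tru_c = tru - tru.mean(axis=1, keepdims=True)
    num = (est_c * tru_c).sum(axis=1)
    den = np.sqrt((est_c ** 2).sum(axis=1) * (tru_c ** 2).sum(axis=1))
    out = np.zeros(est.shape[0])
    ok = den > 0
    out[ok] = (num[ok] / den[ok]) ** 2
    return out


def haplotype_stats(library: HaplotypeLibrary) -> HaplotypeStats:
    """Library summary: distinct haplotypes per segment and sharing."""
    counts = [seg.counts[: seg.n_entries] for seg in library.segments]
    n_per_seg = np.array([len(c) for c in counts], dtype=float)
    if n_per_seg.sum() == 0:
        raise ValueError("empty haplotype library")
    total = float(sum(int(c.sum()) for c in counts))
    top = float(max((int(c[0]) if len(c) else 0) for c in counts))
    # share of the single most frequent haplotype among all assignments of
    # its own segment
    shares = [c[0] / c.sum() for c in counts if len(c) and c.sum() > 0]
    return HaplotypeStats(
        mean_haplotypes_per_segment=float(n_per_seg.mean()),
        sd_haplotypes_per_segment=float(n_per_seg.std(ddof=1)) if len(n_per_seg) > 1 else 0.0,
        most_frequent_share=float(np.mean(shares)),
        mean_observations_per_haplotype=total / float(n_per_seg.sum()),
    )


def ld_r2_by_distance(dosage: np.ndarray, marker_map, bins,
                      max_pairs_per_bin: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Mean squared genotype correlation binned by map distance.

    Marker pairs are drawn within chromosomes, their squared Pearson
    correlation of dosages computed across individuals and averaged within
    each distance bin (bin edges in Morgans).  Pairs are subsampled to at
    most ``max_pairs_per_bin`` per bin for tractability.
    """
    rng = np.random.default_rng(seed)
    dosage = np.asarray(dosage, dtype=np.float64)
    edges = np.asarray(bins, dtype=float)
    sums = np.zeros(len(edges) - 1)
    ns = np.zeros(len(edges) - 1, dtype=np.int64)
    starts, stops = marker_map.chrom_bounds()
    centered = dosage - dosage.mean(axis=0, keepdims=True)
    var = (centered ** 2).sum(axis=0)
    target = max_pairs_per_bin * (len(edges) - 1)
    n_draw = 20 * target
    for lo, hi in zip(starts, stops):
        k = hi - lo
        if k < 2:
            continue
        i = rng.integers(lo, hi, size=n_draw // len(starts))
        j = rng.integers(lo, hi, size=n_draw // len(starts))
        keep = i < j
        i, j = i[keep], j[keep]
        d = marker_map.position[j] - marker_map.position[i]
        which = np.digitize(d, edges) - 1
        for b in range(len(edges) - 1):
            sel = np.flatnonzero(which == b)
            if sel.size == 0:
                continue
            room = max_pairs_per_bin - ns[b]
            if room <= 0:
                continue
            sel = sel[:room]
            ii, jj = i[sel], j[sel]
            ok = (var[ii] > 0) & (var[jj] > 0)
            ii, jj = ii[ok], jj[ok]
            if ii.size == 0:
                continue
            num = (centered[:, ii] * centered[:, jj]).sum(axis=0)
            r2 = (num ** 2) / (var[ii] * var[jj])
            sums[b] += r2.sum()
            ns[b] += r2.size
    mid = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return pd.DataFrame({"distance_morgans": mid, "mean_r2": mean_r2, "n_pairs": ns})
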