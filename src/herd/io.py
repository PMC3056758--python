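"""File formats: pedigree, marker map, genotypes, phenotypes, libraries.

Genotype files follow the compact one-line-per-animal dialect: an animal id
followed by a contiguous string of per-marker codes, ``0/1/2`` with ``5``
for missing.  All writers round-trip bit-exactly through their paired
readers.  A minimal VCF converter (GT fields only) is provided for
interoperability; everything else is TSV.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotyper import HaplotypeLibrary, ImputedGenotypes
from .ldsim import Cohort, Density, GenotypeMatrix, MarkerMap, Pedigree

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_genotypes", "write_genotypes",
    "read_marker_map", "write_marker_map",
    "read_phenotypes", "write_phenotypes",
    "write_haplotype_library", "read_haplotype_library",
    "write_imputed", "write_report",
    "genotypes_to_vcf", "genotypes_from_vcf",
    "write_provenance",
]

_COHORT_NAMES = {c.name.lower(): int(c) for c in Cohort}
_DENSITY_NAMES = {d.name.lower(): int(d) for d in Density}
_UNKNOWN_PARENT = {"0", ".", "", "NA"}


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\tcohort\tdensity\n")
        for a in range(pedigree.n_animals):
            s = pedigree.ids[pedigree.sire[a]] if pedigree.sire[a] >= 0 else "."
            d = pedigree.ids[pedigree.dam[a]] if pedigree.dam[a] >= 0 else "."
            fh.write(f"{pedigree.ids[a]}\t{s}\t{d}\t"
                     f"{Cohort(pedigree.cohort[a]).name.lower()}\t"
                     f"{Density(pedigree.density[a]).name.lower()}\n")


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV (animal, sire, dam, cohort, density).

    '0' or '.' denote unknown parents.  Rows may appear in any order; the
    pedigree is validated (unique ids, resolvable parents, no cycles — a
    cycle is reported with its member chain).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree file needs columns {sorted(required)}")
    ids = df["animal"].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        dupes = df["animal"][df["animal"].duplicated()].iloc[0]
        raise ValueError(f"duplicate animal id {dupes!r} in pedigree")
    index = {a: i for i, a in enumerate(ids)}

    def parent_idx(col):
        out = np.full(len(ids), -1, dtype=np.int32)
        for i, v in enumerate(df[col]):
            if v in _UNKNOWN_PARENT:
                continue
            if v not in index:
                raise ValueError(f"animal {ids[i]!r} names unknown parent {v!r}")
            out[i] = index[v]
        return out

    cohort = np.asarray(
        [_COHORT_NAMES.get(str(v).lower(), int(Cohort.ANCESTOR))
         for v in df.get("cohort", pd.Series(["ancestor"] * len(ids)))],
        dtype=np.int8)
    density = np.asarray(
        [_DENSITY_NAMES.get(str(v).lower(), int(Density.NONE))
         for v in df.get("density", pd.Series(["none"] * len(ids)))],
        dtype=np.int8)
    return Pedigree(ids, parent_idx("sire"), parent_idx("dam"), cohort, density)


def write_genotypes(gm: GenotypeMatrix, ids, path) -> None:
    codes = np.where(gm.missing, 5, gm.codes).astype(np.uint8) + ord("0")
    with open(path, "w") as fh:
        for i, animal in enumerate(ids):
            fh.write(f"{animal} {codes[i].tobytes().decode('ascii')}\n")


def read_genotypes(path, marker_map: MarkerMap | None = None):
    """Read the id + code-string genotype dialect.

    Returns (ids, GenotypeMatrix).  Code 5 becomes a masked entry with
    matching code 1; anything but 0/1/2/5 fails with its line number.
    """
    ids, rows, masks = [], [], []
    n_expected = marker_map.n_markers if marker_map is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                animal, codes = line.split(maxsplit=1)
            except ValueError:
                raise ValueError(f"line {lineno}: expected 'id codes'") from None
            codes = codes.strip()
            arr = np.frombuffer(codes.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = ~np.isin(arr, (0, 1, 2, 5))
            if np.any(bad):
                pos = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"line {lineno}: invalid genotype code {codes[pos]!r} at marker {pos + 1}")
            if n_expected is not None and arr.size != n_expected:
                raise ValueError(
                    f"line {lineno}: {arr.size} codes but map has {n_expected} markers")
            miss = arr == 5
            rows.append(np.where(miss, 1, arr).astype(np.int8))
            masks.append(miss)
            ids.append(animal)
    if not rows:
        raise ValueError(f"no genotype records in {path}")
    return np.asarray(ids, dtype=object), GenotypeMatrix(np.vstack(rows), np.vstack(masks))


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "position_morgans", "allele_freq"}
    if not need.issubset(df.columns):
        raise ValueError(f"marker map needs columns {sorted(need)}")
    n = len(df)
    # phase signs are a simulation-internal property; files do not carry them
    return MarkerMap(df["chrom"].to_numpy(np.int32),
                     df["position_morgans"].to_numpy(float),
                     df["allele_freq"].to_numpy(float),
                     np.zeros(n, dtype=bool))


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[["animal_id", "y", "rel_prog"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"animal_id", "y", "rel_prog"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype file needs columns {sorted(need)}")
    return df


def write_haplotype_library(library: HaplotypeLibrary, ids, path_entries, path_assign) -> None:
    """Entries file (per-segment header + indexed allele strings) and
    per-animal assignment file (animal, segment, hap1, hap2)."""
    with open(path_entries, "w") as fh:
        for si, seg in enumerate(library.segments):
            fh.write(f"#segment {si} chrom {seg.chrom} start {seg.start + 1} "
                     f"stop {seg.stop}\n")
            for i in range(seg.n_entries):
                alleles = (seg.lib[i].astype(np.uint8) + ord("0")).tobytes().decode("ascii")
                fh.write(f"{i + 1}\t{int(seg.counts[i])}\t{alleles}\n")
    with open(path_assign, "w") as fh:
        fh.write("animal\tsegment\thap1\thap2\n")
        for si, seg in enumerate(library.segments):
            for a in range(len(seg.hp)):
                if seg.hp[a] >= 0 or seg.hm[a] >= 0:
                    fh.write(f"{ids[a]}\t{si}\t{int(seg.hp[a]) + 1}\t{int(seg.hm[a]) + 1}\n")


def read_haplotype_library(path_entries) -> list[dict]:
    """Entries file back as a list of {chrom, start, stop, entries, counts}."""
    segments: list[dict] = []
    with open(path_entries) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#segment"):
                parts = line.split()
                segments.append({"chrom": int(parts[3]), "start": int(parts[5]) - 1,
                                 "stop": int(parts[7]), "entries": [], "counts": []})
            else:
                idx, count, alleles = line.split("\t")
                arr = np.frombuffer(alleles.encode("ascii"), dtype=np.uint8) - ord("0")
                segments[-1]["entries"].append(arr.astype(np.int8))
                segments[-1]["counts"].append(int(count))
    for s in segments:
        s["entries"] = np.vstack(s["entries"]) if s["entries"] else np.empty((0, 0), np.int8)
        s["counts"] = np.asarray(s["counts"], dtype=np.int64)
    return segments


def write_imputed(imputed: ImputedGenotypes, ids, path) -> None:
    prov_code = np.array(["O", "I", "H", "F"])
    with open(path, "w") as fh:
        fh.write("animal\tcall_rate\tdosages\tprovenance\n")
        for i, animal in enumerate(ids):
            d = ",".join(f"{x:.3f}" for x in imputed.dosage[i])
            p = "".join(prov_code[imputed.provenance[i]])
            fh.write(f"{animal}\t{imputed.call_rate[i]:.4f}\t{d}\t{p}\n")


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", float_format="%.4f")


# ---------------------------------------------------------------------------
# VCF interoperability (GT only)
# ---------------------------------------------------------------------------

def genotypes_to_vcf(imputed_or_gm, ids, marker_map: MarkerMap, path,
                     phased: bool = False) -> None:
    """Export genotypes (or phased imputed haplotypes) as an uncompressed VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in np.unique(marker_map.chrom):
        header.contigs.add(str(int(c) + 1))
    for animal in ids:
        header.add_sample(str(animal))
    local = marker_map.local_index()
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in range(marker_map.n_markers):
            rec = vf.new_record(
                contig=str(int(marker_map.chrom[j]) + 1),
                start=int(round(marker_map.position[j] * 1_000_000)) + int(local[j]),
                alleles=("A", "B"), id=f"M{j + 1}")
            if phased:
                hp = imputed_or_gm.hap_pat[:, j]
                hm = imputed_or_gm.hap_mat[:, j]
                for i, animal in enumerate(ids):
                    a1 = None if hp[i] == 1 else int(hp[i]) // 2
                    a2 = None if hm[i] == 1 else int(hm[i]) // 2
                    rec.samples[str(animal)]["GT"] = (a1, a2)
                    rec.samples[str(animal)].phased = True
            else:
                codes = imputed_or_gm.codes[:, j]
                miss = imputed_or_gm.missing[:, j]
                gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
                for i, animal in enumerate(ids):
                    rec.samples[str(animal)]["GT"] = (None, None) if miss[i] else gt[int(codes[i])]
            vf.write(rec)


def genotypes_from_vcf(path) -> tuple[np.ndarray, GenotypeMatrix]:
    """Import unphased GT codes from a VCF into the package's matrix form."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        ids = np.asarray(list(vf.header.samples), dtype=object)
        rows, masks = [], []
        for rec in vf:
            col = np.ones(len(ids), dtype=np.int8)
            miss = np.zeros(len(ids), dtype=bool)
            for i, animal in enumerate(ids):
                gt = rec.samples[str(animal)]["GT"]
                if gt is None or any(g is None for g in gt):
                    miss[i] = True
                else:
                    col[i] = int(sum(gt))
            rows.append(col)
            masks.append(miss)
    codes = np.vstack(rows).T.copy()
    missing = np.vstack(masks).T.copy()
    codes[missing] = 1
    return ids, GenotypeMatrix(codes, missing)


def write_provenance(path, config: dict, seed) -> None:
    """Machine-readable record of what produced a run's outputs."""
    import herd

    payload = {
        "package": "herd",
        "version": getattr(herd, "__version__", "unknown"),
        "python": sys.version.split()[0],
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
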