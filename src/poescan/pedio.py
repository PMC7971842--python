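"""Pedigree-format genotype I/O and trio assembly.

Reads and writes classic whitespace-delimited PED/MAP files (six fixed
columns — family ID, individual ID, father ID, mother ID, sex, phenotype —
followed by one allele pair per SNP) and a tab-separated SNP annotation
table.  Families are reduced to case trios: one affected child plus
whichever parents were genotyped.  Genotypes are stored as minor-allele
dosages (0/1/2, ``-1`` for missing) in rectangular per-member matrices.

Mendelian consistency is deliberately NOT checked here; the QC layer owns
that, so the reader accepts inconsistent trios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MISSING = -1

PATHWAYS = ("folate", "homocysteine", "transsulfuration", "other")

_ANNOT_COLUMNS = ("snp_id", "chr", "pos", "minor", "major", "gene", "pathway")


class PedParseError(ValueError):
    """Raised for a malformed PED/MAP line; message names the line number."""


@dataclass(frozen=True)
class SnpMeta:
    """Annotation for one biallelic SNP.

    ``allele_minor``/``allele_major`` define the dosage orientation: dosage
    counts copies of the minor allele.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str
    gene: str = ""
    pathway: str = "other"

    def __post_init__(self) -> None:
        if self.allele_minor == self.allele_major:
            raise ValueError(
                f"{self.snp_id}: minor and major allele are both "
                f"{self.allele_minor!r}"
            )
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")


@dataclass(frozen=True)
class TrioGenotype:
    """One family's minor-allele dosages at a single SNP.

    ``m``, ``f``, ``c`` are mother/father/child dosages in {0, 1, 2} or
    ``MISSING``.  The child is never missing for records entering model
    fitting (families are ascertained on a genotyped case child).
    """

    family_id: str
    m: int
    f: int
    c: int
    stratum: str = "ALL"


@dataclass
class Panel:
    """Rectangular family-by-SNP dosage container.

    Every family has a dosage slot (possibly ``MISSING``) for every SNP in
    each of the three member matrices ``m``/``f``/``c`` (mother, father,
    child).  A parent absent from the pedigree has ``*_present`` False and
    an all-missing row.
    """

    snps: list[SnpMeta]
    family_ids: list[str]
    m: np.ndarray  # (n_families, n_snps) int8, -1 missing
    f: np.ndarray
    c: np.ndarray
    mother_present: np.ndarray  # (n_families,) bool
    father_present: np.ndarray
    strata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strata:
            self.strata = ["ALL"] * len(self.family_ids)
        n_fam, n_snp = len(self.family_ids), len(self.snps)
        for name in ("m", "f", "c"):
            arr = np.asarray(getattr(self, name), dtype=np.int8)
            if arr.shape != (n_fam, n_snp):
                raise ValueError(
                    f"{name} matrix has shape {arr.shape}, "
                    f"expected ({n_fam}, {n_snp})"
                )
            setattr(self, name, arr)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def trios_for_snp(self, snp_index: int) -> list[TrioGenotype]:
        """All families' trio records at one SNP (child may be missing here;
        model-facing callers filter on ``c != MISSING``)."""
        return [
            TrioGenotype(
                family_id=self.family_ids[i],
                m=int(self.m[i, snp_index]),
                f=int(self.f[i, snp_index]),
                c=int(self.c[i, snp_index]),
                stratum=self.strata[i],
            )
            for i in range(self.n_families)
        ]

    def iter_snps(self) -> Iterator[tuple[SnpMeta, list[TrioGenotype]]]:
        for k, meta in enumerate(self.snps):
            yield meta, self.trios_for_snp(k)

    def subset_snps(self, indices: Sequence[int]) -> "Panel":
        idx = list(indices)
        return Panel(
            snps=[self.snps[k] for k in idx],
            family_ids=list(self.family_ids),
            m=self.m[:, idx].copy(),
            f=self.f[:, idx].copy(),
            c=self.c[:, idx].copy(),
            mother_present=self.mother_present.copy(),
            father_present=self.father_present.copy(),
            strata=list(self.strata),
        )

    def founder_allele_counts(self, snp_index: int) -> tuple[int, int]:
        """(minor, major) allele counts among genotyped parents."""
        minor = 0
        total = 0
        for mat in (self.m, self.f):
            col = mat[:, snp_index]
            ok = col != MISSING
            minor += int(col[ok].sum())
            total += 2 * int(ok.sum())
        return minor, total - minor


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 4:
                raise PedParseError(
                    f"{map_path}:{lineno}: expected >=4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts[:4]
            rows.append((snp_id, chrom, int(pos)))
    return rows


def _parse_ped_individuals(ped_path: str | Path, n_snps: int):
    """Yield (lineno, fid, iid, father, mother, sex, pheno, alleles)."""
    expected = 6 + 2 * n_snps
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != expected:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {expected} fields "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            fid, iid, father, mother, sex, pheno = parts[:6]
            alleles = parts[6:]
            yield lineno, fid, iid, father, mother, sex, pheno, alleles


def _dosage(a1: str, a2: str, minor: str) -> int:
    if a1 == "0" or a2 == "0":
        return MISSING
    return int(a1 == minor) + int(a2 == minor)


def read_ped(
    ped_path: str | Path,
    map_path: str | Path,
    annotation: Sequence[SnpMeta] | None = None,
    strata: dict[str, str] | None = None,
) -> Panel:
    """Read a case-family PED/MAP pair into a :class:`Panel`.

    Dosages count the minor allele, determined per SNP from founder
    (parental) allele counts unless ``annotation`` fixes the orientation;
    frequency ties are broken toward the ASCII-lowest allele.  ``0 0``
    genotypes become missing.  Each family is reduced to its case child
    (phenotype 2) plus available parents; extra affected children are
    dropped with a warning.  ``strata`` optionally maps family ID to a
    population-group label (default ``"ALL"``).
    """
    snp_rows = _read_map(map_path)
    n_snps = len(snp_rows)

    families: dict[str, dict[str, tuple]] = {}
    order: list[str] = []
    for rec in _parse_ped_individuals(ped_path, n_snps):
        lineno, fid, iid, father, mother, sex, pheno, alleles = rec
        fam = families.setdefault(fid, {})
        if fid not in order:
            order.append(fid)
        if iid in fam:
            raise PedParseError(
                f"{ped_path}:{lineno}: duplicated individual ID {iid!r} "
                f"in family {fid!r}"
            )
        fam[iid] = (father, mother, pheno, alleles)

    # Select one case child per family and link parents by ID.
    trios: list[tuple[str, list | None, list | None, list]] = []
    for fid in order:
        fam = families[fid]
        affected = sorted(iid for iid, rec in fam.items() if rec[2] == "2")
        if not affected:
            raise ValueError(
                f"family {fid!r} has no affected (phenotype 2) individual "
                "in a case-only file"
            )
        if len(affected) > 1:
            warnings.warn(
                f"family {fid!r} has {len(affected)} affected children; "
                f"keeping {affected[0]!r}",
                stacklevel=2,
            )
        child = affected[0]
        father_id, mother_id, _, child_alleles = fam[child]
        father_alleles = fam[father_id][3] if father_id in fam else None
        mother_alleles = fam[mother_id][3] if mother_id in fam else None
        trios.append((fid, mother_alleles, father_alleles, child_alleles))

    # Orient dosages: minor allele from founder counts, or from annotation.
    if annotation is not None:
        if len(annotation) != n_snps:
            raise ValueError(
                f"annotation has {len(annotation)} SNPs, MAP has {n_snps}"
            )
        metas = list(annotation)
    else:
        metas = []
        for k, (snp_id, chrom, pos) in enumerate(snp_rows):
            counts: dict[str, int] = {}
            for _, m_all, f_all, _ in trios:
                for parent in (m_all, f_all):
                    if parent is None:
                        continue
                    for a in parent[2 * k : 2 * k + 2]:
                        if a != "0":
                            counts[a] = counts.get(a, 0) + 1
            alleles = sorted(counts)  # ASCII order breaks frequency ties
            if len(alleles) == 0:
                alleles = ["A", "B"]
            elif len(alleles) == 1:
                alleles = [alleles[0], "B" if alleles[0] != "B" else "C"]
            elif len(alleles) > 2:
                raise PedParseError(
                    f"SNP {snp_id}: more than two alleles observed: {alleles}"
                )
            # minor = least frequent; tie -> ASCII-lowest (sorted order wins)
            a_lo, a_hi = alleles[0], alleles[1]
            if counts.get(a_hi, 0) < counts.get(a_lo, 0):
                minor, major = a_hi, a_lo
            else:
                minor, major = a_lo, a_hi
            metas.append(
                SnpMeta(snp_id=snp_id, chromosome=chrom, position=pos,
                        allele_minor=minor, allele_major=major)
            )

    n_fam = len(trios)
    m = np.full((n_fam, n_snps), MISSING, dtype=np.int8)
    f = np.full((n_fam, n_snps), MISSING, dtype=np.int8)
    c = np.full((n_fam, n_snps), MISSING, dtype=np.int8)
    mother_present = np.zeros(n_fam, dtype=bool)
    father_present = np.zeros(n_fam, dtype=bool)
    for i, (fid, m_all, f_all, c_all) in enumerate(trios):
        mother_present[i] = m_all is not None
        father_present[i] = f_all is not None
        for k in range(n_snps):
            minor = metas[k].allele_minor
            c[i, k] = _dosage(c_all[2 * k], c_all[2 * k + 1], minor)
            if m_all is not None:
                m[i, k] = _dosage(m_all[2 * k], m_all[2 * k + 1], minor)
            if f_all is not None:
                f[i, k] = _dosage(f_all[2 * k], f_all[2 * k + 1], minor)

    family_ids = [t[0] for t in trios]
    strata_list = [
        (strata or {}).get(fid, "ALL") for fid in family_ids
    ]
    return Panel(
        snps=metas,
        family_ids=family_ids,
        m=m, f=f, c=c,
        mother_present=mother_present,
        father_present=father_present,
        strata=strata_list,
    )


def _genotype_str(dosage: int, meta: SnpMeta) -> str:
    if dosage == MISSING:
        return "0 0"
    mi, ma = meta.allele_minor, meta.allele_major
    return {0: f"{ma} {ma}", 1: f"{mi} {ma}", 2: f"{mi} {mi}"}[int(dosage)]


def write_ped(panel: Panel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as a PED/MAP pair re-readable by :func:`read_ped`.

    The child row carries phenotype 2 and points at the parent IDs; absent
    parents are simply not written (their IDs appear as ``0``).
    """
    with open(map_path, "w") as fh:
        for meta in panel.snps:
            fh.write(f"{meta.chromosome}\t{meta.snp_id}\t0\t{meta.position}\n")

    with open(ped_path, "w") as fh:
        for i, fid in enumerate(panel.family_ids):
            mother_id = f"{fid}_m" if panel.mother_present[i] else "0"
            father_id = f"{fid}_f" if panel.father_present[i] else "0"
            rows = []
            if panel.father_present[i]:
                rows.append((father_id, "0", "0", "1", "1", panel.f[i]))
            if panel.mother_present[i]:
                rows.append((mother_id, "0", "0", "2", "1", panel.m[i]))
            rows.append((f"{fid}_c", father_id, mother_id, "0", "2", panel.c[i]))
            for iid, fa, mo, sex, pheno, dosages in rows:
                geno = " ".join(
                    _genotype_str(int(dosages[k]), panel.snps[k])
                    for k in range(panel.n_snps)
                )
                prefix = f"{fid} {iid} {fa} {mo} {sex} {pheno}"
                fh.write(f"{prefix} {geno}".rstrip() + "\n")


def read_annotation(tsv_path: str | Path) -> list[SnpMeta]:
    """Read the SNP annotation table (tab-separated, with header).

    Required columns: snp_id, chr, pos, minor, major, gene, pathway.
    Pathway strings are matched case-insensitively against the known
    pathway names; anything else maps to ``other``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [col for col in _ANNOT_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {', '.join(missing)}")
    metas = []
    for _, row in df.iterrows():
        pathway = str(row["pathway"]).strip().lower()
        if pathway not in PATHWAYS:
            pathway = "other"
        metas.append(
            SnpMeta(
                snp_id=str(row["snp_id"]).strip(),
                chromosome=str(row["chr"]).strip(),
                position=int(row["pos"]),
                allele_minor=str(row["minor"]).strip(),
                allele_major=str(row["major"]).strip(),
                gene=str(row["gene"]).strip(),
                pathway=pathway,
            )
        )
    ids = [meta.snp_id for meta in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate snp_id in annotation")
    return metas


def write_annotation(snps: Sequence[SnpMeta], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chr": [s.chromosome for s in snps],
            "pos": [s.position for s in snps],
            "minor": [s.allele_minor for s in snps],
            "major": [s.allele_major for s in snps],
            "gene": [s.gene for s in snps],
            "pathway": [s.pathway for s in snps],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
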