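"""Genotype, pedigree and phenotype IO plus SNP quality control.

Genotypes travel as a :class:`GenotypeMatrix`: an ``individuals x SNPs``
integer matrix coding each genotype as the number of copies of the SNP's
second allele (0/1/2, ``MISSING`` = -1 for no-calls) together with a marker
map.  Text PLINK ``.ped``/``.map`` is the interchange format; quality control
removes SNPs on minor allele frequency, call rate and a 1-df Hardy-Weinberg
chi-square, in that order of attribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

MISSING = -1
_VALID_ALLELES = set("ACGT120")

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QCReport",
    "PlinkParseError",
    "read_plink_text",
    "write_plink_text",
    "read_pedigree",
    "write_pedigree",
    "hwe_chi2",
    "qc_filter",
]


class PlinkParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """SNP genotypes coded as counts of the second map allele.

    ``snp_map`` columns: ``snp``, ``chrom``, ``cm``, ``bp``, ``allele1``,
    ``allele2``.  Positions are 1-based; within a chromosome the map is kept
    sorted by position.
    """

    codes: np.ndarray
    ids: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        self.ids = np.asarray(self.ids)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        if self.codes.shape[0] != len(self.ids):
            raise ValueError("number of ids does not match codes rows")
        if self.codes.shape[1] != len(self.snp_map):
            raise ValueError("map length does not match codes columns")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.codes[~valid].ravel()[0]
            raise ValueError(f"invalid genotype code {bad}; expected 0/1/2/{MISSING}")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=0)

    def allele2_frequency(self) -> np.ndarray:
        """Frequency of the second allele among non-missing calls (NaN if none)."""
        obs = self.codes != MISSING
        called = obs.sum(axis=0)
        tot = np.where(obs, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, tot / (2.0 * called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele2_frequency()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """(n_snps, 3) counts of codes 0, 1, 2 among non-missing calls."""
        return np.stack([(self.codes == k).sum(axis=0) for k in (0, 1, 2)], axis=1)

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.codes[:, index], self.ids, self.snp_map.iloc[index]
        )

    def take_individuals(self, ids: Sequence) -> "GenotypeMatrix":
        lookup = {iid: k for k, iid in enumerate(self.ids)}
        rows = np.array([lookup[i] for i in ids])
        return GenotypeMatrix(self.codes[rows], np.asarray(ids), self.snp_map)

    def x_linked(self) -> np.ndarray:
        """Boolean mask of SNPs with an X chromosome label."""
        lab = self.snp_map["chrom"].astype(str).str.upper()
        return (lab == "X").to_numpy() | (lab == "CHRX").to_numpy()

    def sort_map(self) -> "GenotypeMatrix":
        order = self.snp_map.sort_values(
            ["chrom", "bp"], kind="stable"
        ).index.to_numpy()
        return self.take_snps(order)


@dataclass
class QCReport:
    """Per-filter attribution of removed SNPs plus per-SNP statistics."""

    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_retained: int
    table: pd.DataFrame  # snp, maf, call_rate, hwe_chi2, hwe_p, removed_by

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- PLINK
def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read text PLINK ``.ped``/``.map`` files.

    The ``.map`` may be the standard 4-column (chrom, snp, cM, bp) or the
    extended 6-column form with allele1/allele2 appended (as written by
    :func:`write_plink_text`).  With a 4-column map, allele1 is the first
    allele encountered in file order and allele2 the second; ``0`` denotes a
    missing allele.  Codes count copies of allele2.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (4, 6):
            raise PlinkParseError(
                f"{map_path}: line {ln}: expected 4 or 6 columns, got {len(parts)}"
            )
        chrom, snp, cm, bp = parts[:4]
        a1, a2 = (parts[4], parts[5]) if len(parts) == 6 else (None, None)
        map_rows.append((snp, chrom, float(cm), int(bp), a1, a2))
    snp_map = pd.DataFrame(
        map_rows, columns=["snp", "chrom", "cm", "bp", "allele1", "allele2"]
    )
    if (snp_map["bp"] <= 0).any():
        raise PlinkParseError(f"{map_path}: non-positive base-pair position")
    m = len(snp_map)

    ids = []
    allele_rows = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise PlinkParseError(
                f"{ped_path}: line {ln}: expected {6 + 2 * m} columns "
                f"(6 + 2 x {m} SNPs), got {len(parts)}"
            )
        alleles = parts[6:]
        for a in alleles:
            if a not in _VALID_ALLELES:
                raise PlinkParseError(
                    f"{ped_path}: line {ln}: invalid allele {a!r}"
                )
        ids.append(parts[1])
        allele_rows.append(alleles)

    n = len(ids)
    al = np.array(allele_rows, dtype="U1").reshape(n, m, 2) if n else np.empty((0, m, 2), dtype="U1")
    a1 = snp_map["allele1"].to_numpy(dtype=object)
    a2 = snp_map["allele2"].to_numpy(dtype=object)
    for j in range(m):
        seen = [a for a in dict.fromkeys(al[:, j, :].ravel().tolist()) if a != "0"]
        if len(seen) > 2:
            raise PlinkParseError(
                f"SNP {snp_map['snp'][j]!r}: more than two alleles observed"
            )
        if a1[j] in (None, "0"):
            a1[j] = seen[0] if seen else "0"
        if a2[j] in (None, "0"):
            rest = [a for a in seen if a != a1[j]]
            a2[j] = rest[0] if rest else "0"
    snp_map["allele1"], snp_map["allele2"] = a1, a2

    codes = np.full((n, m), MISSING, dtype=np.int8)
    if n:
        miss = (al == "0").any(axis=2)
        m1 = al == np.asarray(a1, dtype="U1")[None, :, None]
        m2 = al == np.asarray(a2, dtype="U1")[None, :, None]
        codes = np.where(miss, MISSING, m2.sum(axis=2)).astype(np.int8)
        bad = ~miss & ~(m1 | m2).all(axis=2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PlinkParseError(
                f"individual {ids[i]!r}, SNP {snp_map['snp'][j]!r}: allele not "
                f"matching map alleles {a1[j]}/{a2[j]}"
            )
    return GenotypeMatrix(codes, np.array(ids, dtype=object), snp_map)


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write text PLINK files with the extended 6-column map (round-trip safe)."""
    with open(map_path, "w") as fh:
        for row in g.snp_map.itertuples(index=False):
            fh.write(
                f"{row.chrom} {row.snp} {row.cm:g} {row.bp} "
                f"{row.allele1 or '0'} {row.allele2 or '0'}\n"
            )
    a1 = g.snp_map["allele1"].to_numpy(dtype=object)
    a2 = g.snp_map["allele2"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(g.ids):
            pairs = []
            for j, c in enumerate(g.codes[i]):
                if c == MISSING:
                    pairs.append("0 0")
                elif c == 0:
                    pairs.append(f"{a1[j]} {a1[j]}")
                elif c == 1:
                    pairs.append(f"{a1[j]} {a2[j]}")
                else:
                    pairs.append(f"{a2[j]} {a2[j]}")
            fh.write(f"FAM {iid} 0 0 0 -9 " + " ".join(pairs) + "\n")


# ------------------------------------------------------------------ pedigree
def read_pedigree(path) -> Pedigree:
    """Read a 3-column (id, sire, dam) CSV into a sorted :class:`Pedigree`."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    cols = [c.lower() for c in df.columns]
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise ValueError(f"pedigree CSV missing column {need!r}")
    df.columns = cols
    return Pedigree.from_parent_map(df[["id", "sire", "dam"]].itertuples(index=False))


def write_pedigree(ped: Pedigree, path) -> None:
    def name(k):
        return "" if k < 0 else str(ped.ids[k])

    pd.DataFrame(
        {
            "id": [str(i) for i in ped.ids],
            "sire": [name(s) for s in ped.sire],
            "dam": [name(d) for d in ped.dam],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------------------ QC
def hwe_chi2(n_AA, n_Aa, n_aa):
    """Pearson 1-df chi-square against Hardy-Weinberg proportions.

    Expected counts use the sample allele frequency.  Monomorphic input gives
    (0, 1).  Accepts scalars or aligned arrays.
    """
    n_AA = np.asarray(n_AA, dtype=np.float64)
    n_Aa = np.asarray(n_Aa, dtype=np.float64)
    n_aa = np.asarray(n_aa, dtype=np.float64)
    if (n_AA < 0).any() or (n_Aa < 0).any() or (n_aa < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if (n < 1).any():
        raise ValueError("at least one genotype observation required")
    p = (2 * n_aa + n_Aa) / (2 * n)
    q = 1.0 - p
    exp = np.stack([q**2 * n, 2 * p * q * n, p**2 * n])
    obs = np.stack([n_AA, n_Aa, n_aa])
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
    chi2 = terms.sum(axis=0)
    mono = (p == 0) | (p == 1)
    chi2 = np.where(mono, 0.0, chi2)
    pval = np.where(mono, 1.0, stats.chi2.sf(chi2, df=1))
    if chi2.ndim == 0:
        return float(chi2), float(pval)
    return chi2, pval


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.90,
    hwe_alpha: float = 1e-5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing MAF, call-rate or Hardy-Weinberg criteria.

    Removal uses strict inequalities (``maf < maf_min`` etc.); each removed
    SNP is attributed to the first failing criterion in the order
    MAF -> call rate -> HWE.  MAF and HWE are computed on non-missing calls; a
    SNP with zero calls has undefined MAF and is attributed to call rate.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    maf = g.maf()
    cr = g.call_rate()
    counts = g.genotype_counts()
    any_call = counts.sum(axis=1) >= 1
    chi2 = np.zeros(g.n_snps)
    pval = np.ones(g.n_snps)
    if any_call.any():
        c = counts[any_call]
        chi2[any_call], pval[any_call] = hwe_chi2(c[:, 0], c[:, 1], c[:, 2])

    fail_maf = np.where(np.isnan(maf), False, maf < maf_min)
    fail_cr = cr < callrate_min
    fail_hwe = pval < hwe_alpha
    removed_by = np.full(g.n_snps, "", dtype=object)
    removed_by[fail_hwe] = "hwe"
    removed_by[fail_cr] = "callrate"
    removed_by[fail_maf] = "maf"
    keep = removed_by == ""

    report = QCReport(
        n_input=g.n_snps,
        n_removed_maf=int((removed_by == "maf").sum()),
        n_removed_callrate=int((removed_by == "callrate").sum()),
        n_removed_hwe=int((removed_by == "hwe").sum()),
        n_retained=int(keep.sum()),
        table=pd.DataFrame(
            {
                "snp": g.snp_map["snp"],
                "maf": maf,
                "call_rate": cr,
                "hwe_chi2": chi2,
                "hwe_p": pval,
                "removed_by": removed_by,
            }
        ),
    )
    return g.take_snps(np.flatnonzero(keep)), report
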