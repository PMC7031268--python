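"""Synthetic cattle data: pedigrees, gene-dropped genotypes, polygenic values,
QTN-affected phenotypes and raw fertility records.

The generator emulates the data shape of a dairy-cattle genomic study: a
half-sib-heavy multi-generation pedigree (few sires, many dams per sire),
biallelic SNP genotypes transmitted by Mendelian gene-dropping, polygenic
values sampled parent-to-offspring with inbreeding-adjusted Mendelian
sampling variance, low-heritability trait phenotypes (polygenic variance 1
against residual variance 19) carrying up to three QTN with additive effect
``a`` and dominance effect ``d = h a``, and insemination/calving record
tables with herd and year-month structure and right-censoring.

Founder genotypes are drawn independently per SNP from supplied allele
frequencies by default (no linkage disequilibrium).  Passing a founder
haplotype pool (e.g. coalescent haplotypes, see :mod:`domvar.power`) and
``recombination=True`` instead transmits whole gametes with Haldane
crossovers, which reproduces chip-like LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "SimulationScenario",
    "PolygenicValues",
    "FertilityParams",
    "simulate_pedigree",
    "default_snp_map",
    "gene_drop_genotypes",
    "simulate_polygenic",
    "qtn_effects",
    "simulate_qtn_phenotypes",
    "simulate_fertility_records",
]


@dataclass
class SimulationScenario:
    """One QTN simulation condition.

    ``var_fraction`` is the additive QTN variance as a fraction of the
    polygenic variance ``sigma_u2`` (0.05 = "small", 0.10 = "large");
    ``dominance_ratio`` is ``h = d/a``.
    """

    qtn_positions: tuple = (10_109_903, 20_058_762, 30_039_582)
    qtn_mafs: tuple = (0.43, 0.19, 0.09)
    var_fraction: float = 0.05
    dominance_ratio: float = -1.0
    sigma_u2: float = 1.0
    sigma_e2: float = 19.0
    n_reps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.qtn_positions) != len(self.qtn_mafs):
            raise ValueError("qtn_positions and qtn_mafs must align")
        if self.var_fraction < 0:
            raise ValueError("var_fraction must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class PolygenicValues:
    """Breeding values and the inbreeding coefficients used to sample them."""

    values: np.ndarray
    inbreeding: np.ndarray


# ------------------------------------------------------------------ pedigree
def simulate_pedigree(
    n_founders: int = 380,
    n_generations: int = 4,
    sires_per_generation: int = 25,
    offspring_per_dam: int = 4,
    seed=None,
) -> Pedigree:
    """Discrete-generation half-sib-heavy pedigree.

    Founders are half female, half male.  In each generation every female of
    the previous generation is mated to one of ``sires_per_generation``
    randomly chosen males and produces ``offspring_per_dam`` offspring; sexes
    are assigned half-and-half by permutation so cohort sizes are exact.
    With the defaults the terminal generation holds 6,080 animals, 3,040 of
    them female.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    ids = [f"G0_{k:05d}" for k in range(n_founders)]
    sire = [UNKNOWN] * n_founders
    dam = [UNKNOWN] * n_founders
    sex = np.zeros(n_founders, dtype=np.int8)
    sex[n_founders // 2 :] = 1
    generation = [0] * n_founders
    prev = np.arange(n_founders)

    for g in range(1, n_generations + 1):
        females = prev[sex[prev] == 0]
        males = prev[sex[prev] == 1]
        if len(males) == 0 or len(females) == 0:
            raise ValueError(f"generation {g}: no mating candidates of one sex")
        sires = rng.choice(males, size=min(sires_per_generation, len(males)), replace=False)
        new = []
        for dm in females:
            sr = rng.choice(sires)
            for _ in range(offspring_per_dam):
                idx = len(ids)
                ids.append(f"G{g}_{idx:05d}")
                sire.append(int(sr))
                dam.append(int(dm))
                generation.append(g)
                new.append(idx)
        new = np.array(new)
        new_sex = np.zeros(len(new), dtype=np.int8)
        new_sex[rng.permutation(len(new))[: len(new) // 2]] = 1
        sex = np.concatenate([sex, new_sex])
        prev = new

    return Pedigree(
        np.array(ids, dtype=object),
        np.array(sire),
        np.array(dam),
        sex=sex,
        generation=np.array(generation),
    )


def default_snp_map(
    n_snps: int = 1200, length_bp: int = 43_000_000, chrom: str = "25"
) -> pd.DataFrame:
    """Evenly spaced marker map emulating 50k-chip density on one chromosome."""
    bp = np.linspace(1, length_bp, n_snps).round().astype(np.int64)
    return pd.DataFrame(
        {
            "snp": [f"snp{j:05d}" for j in range(n_snps)],
            "chrom": chrom,
            "cm": bp / 1e6,  # 1 cM ~ 1 Mb
            "bp": bp,
            "allele1": "A",
            "allele2": "G",
        }
    )


# ----------------------------------------------------------------- gene drop
def _gametes_no_linkage(hapA, hapB, rows, rng):
    pick = rng.random(hapA[rows].shape) < 0.5
    return np.where(pick, hapA[rows], hapB[rows])


def gene_drop_genotypes(
    ped: Pedigree,
    founder_freqs=None,
    snp_map: pd.DataFrame | None = None,
    seed=None,
    founder_haplotypes=None,
    recombination: bool = False,
    genotyped=None,
) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree by Mendelian sampling.

    Founder haplotypes are drawn i.i.d. per SNP at ``founder_freqs`` unless a
    ``founder_haplotypes`` pool (2 * n_founders x n_snps, 0/1) is supplied.
    Without recombination each SNP segregates independently; with
    ``recombination=True`` one gamete per parent per meiosis is formed with
    Haldane crossovers using the map's ``cm`` column (fallback 1 cM = 1 Mb).
    ``genotyped`` restricts the returned matrix to a subset of ids.
    """
    rng = np.random.default_rng(seed)
    if snp_map is None:
        if founder_freqs is None:
            raise ValueError("need founder_freqs or snp_map")
        snp_map = default_snp_map(len(np.atleast_1d(founder_freqs)))
    m = len(snp_map)
    n = ped.n
    founders = np.flatnonzero(ped.is_founder)

    hapA = np.zeros((n, m), dtype=np.int8)
    hapB = np.zeros((n, m), dtype=np.int8)
    if founder_haplotypes is not None:
        pool = np.asarray(founder_haplotypes, dtype=np.int8)
        if pool.shape != (2 * len(founders), m):
            raise ValueError(
                f"founder haplotype pool must be (2*{len(founders)}, {m})"
            )
        hapA[founders] = pool[0::2]
        hapB[founders] = pool[1::2]
    else:
        freqs = np.broadcast_to(np.asarray(founder_freqs, dtype=float), (m,))
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("founder frequencies must be in [0, 1]")
        hapA[founders] = rng.random((len(founders), m)) < freqs
        hapB[founders] = rng.random((len(founders), m)) < freqs

    if recombination:
        cm = snp_map["cm"].to_numpy(dtype=float)
        if np.all(cm == 0):
            cm = snp_map["bp"].to_numpy(dtype=float) / 1e6
        rprob = 0.5 * (1.0 - np.exp(-2.0 * np.abs(np.diff(cm)) / 100.0))

        def gamete(parent):
            switches = rng.random(m - 1) < rprob
            phase = np.zeros(m, dtype=bool)
            phase[1:] = np.cumsum(switches) % 2
            if rng.random() < 0.5:
                phase = ~phase
            return np.where(phase, hapB[parent], hapA[parent])

        for i in np.flatnonzero(~ped.is_founder):
            hapA[i] = gamete(ped.dam[i]) if ped.dam[i] != UNKNOWN else (
                rng.random(m) < hapA[founders].mean(axis=0)
            )
            hapB[i] = gamete(ped.sire[i]) if ped.sire[i] != UNKNOWN else (
                rng.random(m) < hapA[founders].mean(axis=0)
            )
    else:
        for level in ped.levels()[1:]:
            dams = ped.dam[level]
            sires = ped.sire[level]
            # unknown parents inherit a random founder-frequency draw
            known_d = dams != UNKNOWN
            known_s = sires != UNKNOWN
            hapA[level] = _gametes_no_linkage(hapA, hapB, np.where(known_d, dams, 0), rng)
            hapB[level] = _gametes_no_linkage(hapA, hapB, np.where(known_s, sires, 0), rng)
            if not known_d.all() or not known_s.all():
                pfound = hapA[founders].mean(axis=0)
                for rows, known in ((level[~known_d], "A"), (level[~known_s], "B")):
                    tgt = hapA if known == "A" else hapB
                    if len(rows):
                        tgt[rows] = rng.random((len(rows), m)) < pfound

    codes = (hapA + hapB).astype(np.int8)
    ids = ped.ids
    if genotyped is not None:
        pos = ped.positions(genotyped)
        codes = codes[pos]
        ids = np.asarray(genotyped)
    return GenotypeMatrix(codes, ids, snp_map)


# ----------------------------------------------------------------- polygenic
def simulate_polygenic(
    ped: Pedigree, sigma_u2: float = 1.0, seed=None, inbreeding=None
) -> PolygenicValues:
    """Sample polygenic values from the oldest to the youngest individual.

    Founders are N(0, sigma_u2).  An individual with one known parent with
    value ``a`` and inbreeding ``F`` is N(a/2, (3/4 - F/4) sigma_u2); with two
    known parents N((a_s + a_d)/2, (1/4 (1 - F_s) + 1/4 (1 - F_d)) sigma_u2).
    """
    rng = np.random.default_rng(seed)
    F = np.asarray(inbreeding if inbreeding is not None else ped.inbreeding())
    vals = np.zeros(ped.n)
    for level in ped.levels():
        s, d = ped.sire[level], ped.dam[level]
        both = (s != UNKNOWN) & (d != UNKNOWN)
        one = (s != UNKNOWN) ^ (d != UNKNOWN)
        none = ~both & ~one
        mean = np.zeros(len(level))
        var = np.full(len(level), sigma_u2, dtype=float)
        if both.any():
            mean[both] = 0.5 * (vals[s[both]] + vals[d[both]])
            var[both] = (
                0.25 * (1 - F[s[both]]) + 0.25 * (1 - F[d[both]])
            ) * sigma_u2
        if one.any():
            par = np.where(s[one] != UNKNOWN, s[one], d[one])
            mean[one] = 0.5 * vals[par]
            var[one] = (0.75 - F[par] / 4.0) * sigma_u2
        vals[level] = mean + rng.standard_normal(len(level)) * np.sqrt(var)
        if none.any() and sigma_u2 == 0:
            vals[level[none]] = 0.0
    return PolygenicValues(values=vals, inbreeding=F)


# ---------------------------------------------------------------------- QTN
def qtn_effects(p: float, f: float, h: float, sigma_u2: float = 1.0) -> tuple[float, float]:
    """Additive and dominance effect sizes for a QTN.

    ``a`` solves ``2 p (1-p) a^2 = f sigma_u2`` (positive by convention) and
    ``d = h a``; the (1-2p)d cross-term is deliberately not part of the
    scaling.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be strictly between 0 and 1")
    if f <= 0:
        raise ValueError("variance fraction must be positive")
    a = float(np.sqrt(f * sigma_u2 / (2.0 * p * (1.0 - p))))
    return a, h * a


def _qtn_values(a: float, d: float, p_allele2: float, orient: str) -> np.ndarray:
    """Genotypic value lookup for codes 0/1/2.

    ``orient="major"`` attaches +a to the major-allele homozygote (the
    heterozygote then deviates toward/away from the common class according to
    the sign of h), ``orient="alt"`` always attaches +a to the code-2
    (second-allele) homozygote.
    """
    if orient not in ("major", "alt"):
        raise ValueError("orient must be 'major' or 'alt'")
    if orient == "alt" or p_allele2 >= 0.5:
        return np.array([-a, d, a])
    return np.array([a, d, -a])


def simulate_qtn_phenotypes(
    g: GenotypeMatrix,
    ped: Pedigree,
    scenario: SimulationScenario,
    seed=None,
    orient: str = "major",
    polygenic: PolygenicValues | None = None,
    return_details: bool = False,
):
    """Phenotype = polygenic + QTN genotypic values + N(0, sigma_e2) residual.

    QTN columns are looked up by base-pair position (nearest map SNP).  The
    additive effect is scaled from the realised sample minor allele frequency
    of each QTN, the target MAF from the scenario serving as fallback when
    the QTN is monomorphic in the sample (with a warning).
    """
    rng = np.random.default_rng(seed)
    poly = polygenic if polygenic is not None else simulate_polygenic(
        ped, scenario.sigma_u2, seed=rng.integers(2**31 - 1)
    )
    pos = ped.positions(g.ids)
    y = poly.values[pos].copy()

    bp = g.snp_map["bp"].to_numpy()
    details = []
    for qtn_bp, target_maf in zip(scenario.qtn_positions, scenario.qtn_mafs):
        j = int(np.argmin(np.abs(bp - qtn_bp)))
        codes = g.codes[:, j]
        p2 = float(codes[codes >= 0].mean() / 2.0) if (codes >= 0).any() else np.nan
        maf = min(p2, 1 - p2)
        if not 0.0 < maf:
            warnings.warn(
                f"QTN at {qtn_bp} bp is monomorphic in the sample; using the "
                "target MAF for the effect size",
                stacklevel=2,
            )
            maf = target_maf
        if scenario.var_fraction == 0:
            a, d = 0.0, 0.0
        else:
            a, d = qtn_effects(maf, scenario.var_fraction, scenario.dominance_ratio,
                               scenario.sigma_u2)
        vals = _qtn_values(a, d, p2 if np.isfinite(p2) else 0.5, orient)
        y = y + np.where(codes >= 0, vals[np.clip(codes, 0, 2)], 0.0)
        details.append(
            {"bp": int(bp[j]), "snp_index": j, "maf": maf, "a": a, "d": d}
        )
    y = y + rng.standard_normal(len(y)) * np.sqrt(scenario.sigma_e2)
    if return_details:
        return y, pd.DataFrame(details)
    return y


# ---------------------------------------------------------- fertility records
@dataclass
class FertilityParams:
    """Means/SDs for the raw fertility traits and record-structure knobs.

    Trait targets follow typical dairy-cattle summaries: heifer
    interval-first-to-last-insemination (IFL) ~30 d, cow
    calving-to-first-insemination (ICF) ~50 d, 1-3 parities per cow, ~15%
    right-censored records.  Skewed day-count traits are gamma distributed
    (matching mean and SD), insemination counts are 1 + Poisson.
    """

    ifl_heifer: tuple = (29.7, 50.7)
    ifl_cow: tuple = (77.5, 35.8)
    icf: tuple = (49.2, 64.5)
    nins_heifer: float = 1.86
    nins_cow: float = 2.34
    censor_rate: float = 0.15
    herd_sd: float = 3.0
    yearmonth_sd: float = 2.0
    age_slope: float = 0.02
    n_yearmonths: int = 24
    max_parity: int = 3


def _gamma(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    return rng.gamma(shape, sd**2 / mean, size)


def simulate_fertility_records(
    ped: Pedigree,
    n_herds: int = 50,
    params: FertilityParams | None = None,
    seed=None,
) -> pd.DataFrame:
    """Raw heifer and cow insemination/calving records for the pedigree's females.

    Every female gets one heifer record; cows get one record per parity
    (1..max, uniform).  Columns: animal, sire, stage, parity, herd,
    year_month, age_first_insemination, age_first_calving, IFL, NINS, ICF,
    censored.  The censoring *flag* is set here; the 21-day / +1-count
    penalty is a separate editing step.
    """
    params = params or FertilityParams()
    rng = np.random.default_rng(seed)
    if ped.sex is None:
        raise ValueError("pedigree has no sex codes")
    females = np.flatnonzero(ped.sex == 0)
    herd_eff = rng.normal(0, params.herd_sd, n_herds)
    ym_eff = rng.normal(0, params.yearmonth_sd, params.n_yearmonths)

    def sire_name(i):
        return str(ped.ids[ped.sire[i]]) if ped.sire[i] != UNKNOWN else ""

    rows = []
    for i in females:
        herd = int(rng.integers(n_herds))
        ym = int(rng.integers(params.n_yearmonths))
        age_fi = float(rng.uniform(400, 550))
        cen = bool(rng.random() < params.censor_rate)
        ifl = float(
            _gamma(rng, *params.ifl_heifer, 1)[0]
            + herd_eff[herd]
            + ym_eff[ym]
            + params.age_slope * (age_fi - 475)
        )
        rows.append(
            {
                "animal": str(ped.ids[i]),
                "sire": sire_name(i),
                "stage": "heifer",
                "parity": np.nan,
                "herd": herd,
                "year_month": ym,
                "age_first_insemination": age_fi,
                "age_first_calving": np.nan,
                "IFL": max(ifl, 0.0),
                "NINS": 1 + int(rng.poisson(params.nins_heifer - 1)),
                "ICF": np.nan,
                "censored": cen,
            }
        )
        n_par = int(rng.integers(1, params.max_parity + 1))
        age_fc = float(rng.uniform(650, 950))
        for par in range(1, n_par + 1):
            herd_c = herd
            ym_c = int(rng.integers(params.n_yearmonths))
            cen = bool(rng.random() < params.censor_rate)
            icf = float(_gamma(rng, *params.icf, 1)[0] + herd_eff[herd_c] + ym_eff[ym_c])
            iflc = float(
                _gamma(rng, *params.ifl_cow, 1)[0]
                + herd_eff[herd_c]
                + ym_eff[ym_c]
                + params.age_slope * (age_fc - 800)
            )
            rows.append(
                {
                    "animal": str(ped.ids[i]),
                    "sire": sire_name(i),
                    "stage": "cow",
                    "parity": par,
                    "herd": herd_c,
                    "year_month": ym_c,
                    "age_first_insemination": np.nan,
                    "age_first_calving": age_fc,
                    "IFL": max(iflc, 0.0),
                    "NINS": 1 + int(rng.poisson(params.nins_cow - 1)),
                    "ICF": max(icf, 0.0),
                    "censored": cen,
                }
            )
    return pd.DataFrame(rows)
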