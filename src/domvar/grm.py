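"""Pedigree and genomic relationship matrices.

The additive genomic matrix follows VanRaden's first method,
``G = ZZ' / sum_j 2 p_j q_j`` with codes centred by twice the allele
frequency.  The dominance matrix is built from heterozygosity deviations:
element (i, j) of ``H`` is ``1 - 2 p_j q_j`` when individual i is
heterozygous at SNP j and ``-2 p_j q_j`` otherwise, and
``D = HH' / sum_j 2 p_j q_j (1 - 2 p_j q_j)``.  Under Hardy-Weinberg
proportions both matrices have unit mean diagonal.  Allele frequencies are
the observed sample frequencies; SNPs with an X chromosome label are
excluded from both genomic matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "RelMatrix",
    "inbreeding_coefficients",
    "pedigree_a",
    "genomic_g",
    "genomic_d",
]


@dataclass
class RelMatrix:
    """Symmetric relationship matrix with its id index and scaling metadata."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # pedigree-additive | genomic-additive | genomic-dominance
    denominator: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = np.asarray(self.ids)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id index")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def add_ridge(self, eps: float) -> "RelMatrix":
        v = self.values.copy()
        v[np.diag_indices_from(v)] += eps
        meta = dict(self.meta, ridge=self.meta.get("ridge", 0.0) + eps)
        return RelMatrix(v, self.ids, self.kind, self.denominator, meta)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-individual inbreeding coefficients (founders 0) in pedigree order."""
    return ped.inbreeding()


def pedigree_a(ped: Pedigree, ids=None) -> RelMatrix:
    """Tabular-method numerator relationship matrix, restricted to ``ids``."""
    if ids is None:
        ids = ped.ids
    A = ped.additive_relationship(ids=ids).astype(np.float64)
    return RelMatrix(A, np.asarray(ids), "pedigree-additive")


def _autosomal_frequencies(g: GenotypeMatrix, exclude_x: bool):
    keep = ~g.x_linked()
    codes = g.codes[:, keep] if exclude_x else g.codes
    if not exclude_x:
        keep = np.ones(g.n_snps, dtype=bool)
    obs = codes != MISSING
    called = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs, codes, 0).sum(axis=0) / (2.0 * np.maximum(called, 1))
    p[called == 0] = np.nan
    poly = (p > 0) & (p < 1)
    if (~poly & ~np.isnan(p)).any():
        warnings.warn(
            f"{int((~poly & ~np.isnan(p)).sum())} monomorphic SNP(s) dropped "
            "from relationship matrix",
            stacklevel=3,
        )
    use = poly & ~np.isnan(p)
    if not use.any():
        raise ValueError("no polymorphic autosomal SNPs: zero denominator")
    return codes[:, use].astype(np.float64), p[use], obs[:, use]


def genomic_g(g: GenotypeMatrix, exclude_x: bool = True) -> RelMatrix:
    """VanRaden method-1 additive genomic relationship matrix.

    Missing codes are mean-imputed (to ``2p``) before centring, so they
    contribute nothing to Z.
    """
    codes, p, obs = _autosomal_frequencies(g, exclude_x)
    Z = np.where(obs, codes, 2 * p) - 2 * p
    denom = float(np.sum(2 * p * (1 - p)))
    G = (Z @ Z.T) / denom
    return RelMatrix(
        G, g.ids, "genomic-additive", denominator=denom, meta={"n_snps": len(p)}
    )


def genomic_d(g: GenotypeMatrix, exclude_x: bool = True) -> RelMatrix:
    """Dominance genomic relationship matrix from heterozygosity deviations.

    A missing call contributes 0 to H (its expected deviation under
    Hardy-Weinberg proportions).
    """
    codes, p, obs = _autosomal_frequencies(g, exclude_x)
    tpq = 2 * p * (1 - p)
    H = np.where(codes == 1, 1.0 - tpq, -tpq)
    H = np.where(obs, H, 0.0)
    denom = float(np.sum(tpq * (1 - tpq)))
    if denom <= 0:
        raise ValueError("zero dominance denominator")
    D = (H @ H.T) / denom
    return RelMatrix(
        D, g.ids, "genomic-dominance", denominator=denom, meta={"n_snps": len(p)}
    )
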