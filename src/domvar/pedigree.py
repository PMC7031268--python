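"""Pedigree container, inbreeding coefficients and the numerator relationship matrix.

A :class:`Pedigree` stores individuals in topological order (parents before
offspring), which every downstream algorithm relies on: the tabular method for
the additive relationship matrix ``A``, Wright's inbreeding coefficients
``F = diag(A) - 1``, gene-dropping and polygenic sampling.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

UNKNOWN = -1

__all__ = ["Pedigree", "UNKNOWN"]


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Parameters
    ----------
    ids
        Individual identifiers, in topological order (parents precede
        offspring).  Use :meth:`from_parent_map` to build from unordered
        records.
    sire, dam
        Integer positions of each individual's parents within ``ids``;
        ``UNKNOWN`` (-1) for a missing parent.
    sex
        Optional per-individual sex code (0 = female, 1 = male); used by the
        mating simulator, ignored elsewhere.
    generation
        Optional generation index (founders = 0).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    _F: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == n):
            raise ValueError("ids, sire and dam must have equal length")
        for par in (self.sire, self.dam):
            bad = (par >= np.arange(n)) & (par != UNKNOWN)
            if bad.any():
                raise ValueError(
                    f"pedigree not topologically sorted: individual "
                    f"{self.ids[np.argmax(bad)]!r} precedes its parent"
                )

    # ------------------------------------------------------------------ build
    @classmethod
    def from_parent_map(
        cls,
        records: Iterable[tuple[object, object, object]],
        sex: Mapping[object, int] | None = None,
    ) -> "Pedigree":
        """Build a sorted pedigree from (id, sire, dam) records.

        Unknown parents may be encoded as ``0``, ``"0"``, ``""``, ``None`` or
        NaN.  Individuals appearing only as parents are added as founders.
        Raises ``ValueError`` naming an individual on the cycle if the
        parentage graph is cyclic.
        """

        def _norm(v):
            if v is None:
                return None
            if isinstance(v, float) and np.isnan(v):
                return None
            if str(v).strip() in ("", "0", "nan"):
                return None
            return str(v).strip()

        parents: dict[str, tuple[str | None, str | None]] = {}
        for rec in records:
            iid, s, d = (_norm(rec[0]), _norm(rec[1]), _norm(rec[2]))
            if iid is None:
                raise ValueError("pedigree record with empty individual id")
            parents[iid] = (s, d)
        for iid, (s, d) in list(parents.items()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)

        ts = graphlib.TopologicalSorter(
            {i: [p for p in ps if p is not None] for i, ps in parents.items()}
        )
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as err:
            cycle = err.args[1]
            raise ValueError(
                f"pedigree contains a cycle through individual {cycle[0]!r}"
            ) from err

        pos = {iid: k for k, iid in enumerate(order)}
        sire_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
        for iid in order:
            s, d = parents[iid]
            if s is not None:
                sire_idx[pos[iid]] = pos[s]
            if d is not None:
                dam_idx[pos[iid]] = pos[d]
        sex_arr = None
        if sex is not None:
            sex_arr = np.array([sex.get(i, -1) for i in order], dtype=np.int8)
        return cls(np.array(order, dtype=object), sire_idx, dam_idx, sex=sex_arr)

    # ------------------------------------------------------------- properties
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def positions(self, ids: Sequence) -> np.ndarray:
        """Map external identifiers to internal (topological) positions."""
        lookup = {iid: k for k, iid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"individual {err.args[0]!r} not in pedigree") from err

    def levels(self) -> list[np.ndarray]:
        """Group individuals into dependency levels (founders first).

        Within one level no individual is the parent of another, so sampling
        and transmission can be vectorised level by level.
        """
        depth = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            s, d = self.sire[i], self.dam[i]
            ds = depth[s] + 1 if s != UNKNOWN else 0
            dd = depth[d] + 1 if d != UNKNOWN else 0
            depth[i] = max(ds, dd)
        return [np.flatnonzero(depth == lev) for lev in range(depth.max() + 1)]

    # ------------------------------------------------------------ relatedness
    def additive_relationship(
        self, ids: Sequence | None = None, dtype=None
    ) -> np.ndarray:
        """Numerator relationship matrix by the tabular method.

        The matrix is computed through *all* ancestors and then restricted to
        ``ids`` (default: everyone, in pedigree order).  ``dtype`` defaults to
        float64 below 6,000 individuals and float32 above (the entries are
        small dyadic rationals, so float32 is exact for shallow pedigrees and
        ~1e-7 accurate otherwise).
        """
        n = self.n
        if dtype is None:
            dtype = np.float64 if n <= 6000 else np.float32
        A = np.zeros((n, n), dtype=dtype)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s != UNKNOWN and d != UNKNOWN:
                row = 0.5 * (A[s, :i] + A[d, :i])
                aii = 1.0 + 0.5 * A[s, d]
            elif s != UNKNOWN or d != UNKNOWN:
                p = s if s != UNKNOWN else d
                row = 0.5 * A[p, :i]
                aii = 1.0
            else:
                row = None
                aii = 1.0
            if row is not None:
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = aii
        self._F = np.asarray(np.diag(A), dtype=np.float64) - 1.0
        if ids is None:
            return A
        pos = self.positions(ids)
        return A[np.ix_(pos, pos)]

    def inbreeding(self) -> np.ndarray:
        """Wright's inbreeding coefficients, ``F = diag(A) - 1``."""
        if self._F is None:
            n = self.n
            # diagonal-only tabular pass still needs off-diagonals of ancestor
            # rows, so just run the full tabular method once and cache F
            self.additive_relationship(ids=self.ids[:0])
        return self._F
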