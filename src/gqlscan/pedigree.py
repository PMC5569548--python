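"""Pedigree handling and the numerator relationship matrix (NRM).

The additive (numerator) relationship matrix ``A`` holds expected additive
genetic relationships between animals derived from the pedigree: diagonal
entries are ``1 + F_i`` (``F_i`` the inbreeding coefficient) and off-diagonals
follow the standard tabular recursion over parents.  The association test
weights observations by the inverse of the ``A`` submatrix restricted to the
analyzed animals, so this module also provides subsetting and dense inversion
with a conditioning guard.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "InverseRelationship",
    "read_pedigree",
    "write_pedigree",
    "build_relationship_matrix",
    "subset_and_invert",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered animal/sire/dam records.

    ``records`` is a list of ``(animal, sire, dam)`` string triples with
    ``None`` for an unknown parent.  Parents named but never listed as animals
    are auto-promoted to founder records.  Construction fails on duplicate
    animal ids and on ancestry cycles.
    """

    records: tuple[tuple[str, str | None, str | None], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {a: i for i, (a, _, _) in enumerate(self.records)}
        )

    @classmethod
    def from_records(
        cls, rows: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        seen: set[str] = set()
        parents: dict[str, tuple[str | None, str | None]] = {}
        for animal, sire, dam in rows:
            animal = str(animal).strip()
            if not animal or animal == UNKNOWN:
                raise PedigreeError(f"invalid animal id {animal!r}")
            if animal in seen:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            seen.add(animal)
            parents[animal] = (_norm_parent(sire), _norm_parent(dam))
        # promote unlisted parents to founders
        for sire, dam in list(parents.values()):
            for p in (sire, dam):
                if p is not None and p not in parents:
                    parents[p] = (None, None)
        sorter = graphlib.TopologicalSorter(
            {a: [p for p in ps if p is not None] for a, ps in parents.items()}
        )
        try:
            order = list(sorter.static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1]
            raise PedigreeError(
                f"pedigree contains an ancestry cycle involving {cycle[0]!r}"
            ) from exc
        return cls(tuple((a, *parents[a]) for a in order))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(a for a, _, _ in self.records)

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(a for a, s, d in self.records if s is None and d is None)

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        _, s, d = self.records[self._index[animal]]
        return s, d

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal: str) -> bool:
        return animal in self._index


def _norm_parent(p: str | None) -> str | None:
    if p is None:
        return None
    p = str(p).strip()
    return None if p in ("", UNKNOWN, "nan", "NA") else p


def read_pedigree(path) -> Pedigree:
    """Read a 3-column animal/sire/dam file (tab or comma, optional header)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"pedigree file needs 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    first = [str(v).lower() for v in df.iloc[0]]
    if any(k in first[0] for k in ("animal", "id")) or "sire" in first[1]:
        df = df.iloc[1:]
    rows = [
        (str(a), str(s), str(d))
        for a, s, d in df.itertuples(index=False, name=None)
    ]
    return Pedigree.from_records(rows)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\n")
        for a, s, d in ped.records:
            fh.write(f"{a}\t{s or UNKNOWN}\t{d or UNKNOWN}\n")


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix over an ordered id list."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        object.__setattr__(self, "values", v)

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def submatrix(self, ids) -> "RelationshipMatrix":
        ids = tuple(ids)
        pos = {a: k for k, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"ids not in relationship matrix: {missing[:5]}")
        idx = np.array([pos[a] for a in ids])
        return RelationshipMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.ids),
                     columns=list(self.ids)).to_csv(path, sep="\t")


@dataclass(frozen=True)
class InverseRelationship:
    """Inverse of an analyzed-subset relationship matrix."""

    ids: tuple[str, ...]
    values: np.ndarray


def build_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Build ``A`` for every animal in the pedigree by the tabular method.

    Processing in topological order, for animal ``i`` with parents ``s, d``:
    ``a_ij = (a_sj + a_dj) / 2`` for every earlier ``j`` (missing parent
    contributes 0) and ``a_ii = 1 + a_sd / 2``.  Founders have ``a_ii = 1``.
    """
    n = len(ped)
    ids = ped.ids
    pos = {a: i for i, a in enumerate(ids)}
    A = np.zeros((n, n))
    for i, (_, sire, dam) in enumerate(ped.records):
        si = pos[sire] if sire is not None else None
        di = pos[dam] if dam is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None
                         else 0.0)
    return RelationshipMatrix(ids, A)


def subset_and_invert(
    A: RelationshipMatrix,
    ids,
    cond_threshold: float = 1e10,
) -> InverseRelationship:
    """Invert the ``A`` submatrix for ``ids`` (rows/cols in requested order).

    Raises ``np.linalg.LinAlgError`` when the submatrix is singular or its
    condition number exceeds ``cond_threshold`` (e.g. duplicated identical
    animals).
    """
    sub = A.submatrix(ids)
    cond = np.linalg.cond(sub.values)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise np.linalg.LinAlgError(
            f"relationship submatrix ill-conditioned (cond={cond:.3g})"
        )
    return InverseRelationship(sub.ids, np.linalg.inv(sub.values))
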