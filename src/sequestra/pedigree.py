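"""Pedigree parsing, validation and additive-genetic bookkeeping.

A :class:`Pedigree` is an ordered collection of animals in which every parent
precedes all of its offspring.  On top of that ordering the module computes the
classical quantities of quantitative genetics used by the animal model:

* the additive (numerator) relationship matrix **A** by Henderson's tabular
  method,
* per-animal inbreeding coefficients ``F_i = A_ii - 1``,
* per-animal Mendelian sampling standard deviations ``s_i`` — the standard
  deviation of the deviation of an animal's breeding value from its parental
  mean, ``sqrt(0.5 - 0.25 (F_sire + F_dam))`` when both parents are known.

Unknown parents are treated as unrelated, non-inbred founders (the standard
BLUP convention).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "CycleError",
    "PedigreeRecord",
    "Pedigree",
    "read_pedigree",
    "inbreeding_coefficients",
    "additive_relationship",
    "mendelian_sampling_sd",
]

SEXES = ("male", "female", "unknown")
STATUSES = ("affected", "unaffected", "unknown")

#: tokens interpreted as "parent unknown" by default when reading files
DEFAULT_MISSING_TOKENS = ("0", "", "NA", "na", ".", "-")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate ids, bad parents, ...)."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle (an animal is its own ancestor)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identity, parents, sex, birth year and phenotype status."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    birth_year: int | None = None
    status: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("animal id must be a non-empty string")
        if self.sire == self.id or self.dam == self.id:
            raise CycleError(f"animal {self.id!r} listed as its own parent")
        if self.sire is not None and self.sire == self.dam:
            raise PedigreeError(
                f"animal {self.id!r} has identical sire and dam {self.sire!r} "
                "(self-fertilization is not modelled)"
            )
        if self.sex not in SEXES:
            raise PedigreeError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.status not in STATUSES:
            raise PedigreeError(
                f"status must be one of {STATUSES}, got {self.status!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Validated, topologically sorted pedigree.

    Parameters
    ----------
    records:
        Animal records in any order.  Parent references must resolve unless
        ``permissive`` is set, in which case animals appearing only as parents
        are materialized as founder records (sires male, dams female).

    Notes
    -----
    The stored order puts every parent before all of its offspring.  Ties are
    broken by input order, then id, so the ordering (and everything derived
    from it) is deterministic and independent of the input row order in the
    sense that the same *set* of records always yields the same matrices.
    """

    def __init__(self, records: Iterable[PedigreeRecord], permissive: bool = True):
        records = list(records)
        seen: dict[str, int] = {}
        for rec in records:
            if rec.id in seen:
                raise PedigreeError(f"duplicate animal id {rec.id!r}")
            seen[rec.id] = 1

        by_id = {r.id: r for r in records}
        # materialize parents that never appear as rows
        extra: list[PedigreeRecord] = []
        for rec in records:
            for parent, sex in ((rec.sire, "male"), (rec.dam, "female")):
                if parent is not None and parent not in by_id:
                    if not permissive:
                        raise PedigreeError(
                            f"parent {parent!r} of {rec.id!r} has no record "
                            "(strict mode)"
                        )
                    founder = PedigreeRecord(id=parent, sex=sex)
                    by_id[parent] = founder
                    extra.append(founder)
        records = extra + records

        self._records = self._toposort(records, by_id)
        self._index = {r.id: i for i, r in enumerate(self._records)}
        n = len(self._records)
        self._sire_idx = np.full(n, -1, dtype=np.int64)
        self._dam_idx = np.full(n, -1, dtype=np.int64)
        for i, rec in enumerate(self._records):
            if rec.sire is not None:
                self._sire_idx[i] = self._index[rec.sire]
            if rec.dam is not None:
                self._dam_idx[i] = self._index[rec.dam]

    @staticmethod
    def _toposort(
        records: Sequence[PedigreeRecord], by_id: Mapping[str, PedigreeRecord]
    ) -> list[PedigreeRecord]:
        # Kahn's algorithm; the ready queue is kept in (input order, id) order
        order_key = {r.id: (i, r.id) for i, r in enumerate(records)}
        children: dict[str, list[str]] = {r.id: [] for r in records}
        indeg = {r.id: 0 for r in records}
        for rec in records:
            for parent in (rec.sire, rec.dam):
                if parent is not None:
                    children[parent].append(rec.id)
                    indeg[rec.id] += 1
        ready = sorted((r.id for r in records if indeg[r.id] == 0), key=order_key.get)
        out: list[PedigreeRecord] = []
        import heapq

        heap = [(order_key[i], i) for i in ready]
        heapq.heapify(heap)
        while heap:
            _, node = heapq.heappop(heap)
            out.append(by_id[node])
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    heapq.heappush(heap, (order_key[child], child))
        if len(out) != len(records):
            stuck = sorted(i for i, d in indeg.items() if d > 0)
            raise CycleError(f"pedigree contains a cycle involving {stuck[:5]}")
        return out

    # -- basic container API ------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> list[PedigreeRecord]:
        return list(self._records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    def index(self, animal_id: str) -> int:
        return self._index[animal_id]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def record(self, animal_id: str) -> PedigreeRecord:
        return self._records[self._index[animal_id]]

    @property
    def sire_indices(self) -> np.ndarray:
        """Position of each animal's sire in pedigree order (-1 = unknown)."""
        return self._sire_idx.copy()

    @property
    def dam_indices(self) -> np.ndarray:
        return self._dam_idx.copy()

    def founders(self) -> list[PedigreeRecord]:
        return [r for r in self._records if r.is_founder]

    def offspring_of(self, parent_id: str) -> list[PedigreeRecord]:
        return [r for r in self._records if parent_id in (r.sire, r.dam)]

    def with_statuses(self, statuses: Mapping[str, str]) -> "Pedigree":
        """Return a copy with phenotype statuses replaced where given."""
        return Pedigree(
            [
                replace(r, status=statuses.get(r.id, r.status))
                for r in self._records
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [r.sire for r in self._records],
                "dam": [r.dam for r in self._records],
                "sex": [r.sex for r in self._records],
                "year": [r.birth_year for r in self._records],
                "status": [r.status for r in self._records],
            }
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["sire"] = df["sire"].fillna("0")
        df["dam"] = df["dam"].fillna("0")
        df.to_csv(path, index=False)


_SEX_ALIASES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}
_STATUS_ALIASES = {
    "affected": "affected", "1": "affected", "case": "affected",
    "unaffected": "unaffected", "0": "unaffected", "healthy": "unaffected",
    "control": "unaffected",
}


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    strict: bool = False,
) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam [, sex, year, status].

    ``dialect`` maps logical names (``"id"``, ``"sire"``, ...) to the file's
    actual column names.  Unknown-parent tokens (``"0"``, ``""``, ``"NA"`` by
    default) become missing.  In strict mode, parent ids without a record of
    their own are an error; otherwise they are materialized as founders.
    """
    cols = {"id": "id", "sire": "sire", "dam": "dam",
            "sex": "sex", "year": "year", "status": "status"}
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required in ("id", "sire", "dam"):
        if cols[required] not in df.columns:
            raise PedigreeError(
                f"required column {cols[required]!r} missing from {path}"
            )
    missing = set(missing_tokens)

    def parent(tok: str) -> str | None:
        tok = tok.strip()
        return None if tok in missing else tok

    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        rid = row[cols["id"]].strip()
        sex = "unknown"
        if cols["sex"] in df.columns:
            sex = _SEX_ALIASES.get(row[cols["sex"]].strip().lower(), "unknown")
        year: int | None = None
        if cols["year"] in df.columns:
            tok = row[cols["year"]].strip()
            if tok not in missing:
                try:
                    year = int(float(tok))
                except ValueError as exc:
                    raise PedigreeError(
                        f"malformed year {tok!r} on line {row_no}"
                    ) from exc
        status = "unknown"
        if cols["status"] in df.columns:
            status = _STATUS_ALIASES.get(
                row[cols["status"]].strip().lower(), "unknown"
            )
        records.append(
            PedigreeRecord(
                id=rid,
                sire=parent(row[cols["sire"]]),
                dam=parent(row[cols["dam"]]),
                sex=sex,
                birth_year=year,
                status=status,
            )
        )
    return Pedigree(records, permissive=not strict)


def _tabular_A(ped: Pedigree) -> np.ndarray:
    """Henderson's tabular method over the whole pedigree (dense)."""
    n = len(ped)
    s, d = ped.sire_indices, ped.dam_indices
    A = np.zeros((n, n))
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj >= 0:
            row += 0.5 * A[sj, :j]
        if dj >= 0:
            row += 0.5 * A[dj, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[sj, dj] if (sj >= 0 and dj >= 0) else 0.0)
    return A


def additive_relationship(
    ped: Pedigree, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Additive relationship matrix A (expected twice-kinship), as a DataFrame.

    ``A_ij = 0.5 (A_{i,sire_j} + A_{i,dam_j})`` for i preceding j, with a
    missing parent contributing 0, and ``A_ii = 1 + 0.5 A_{sire_i, dam_i}``.
    ``subset`` restricts rows/columns to the given ids (in the given order).
    """
    A = _tabular_A(ped)
    ids = ped.ids
    if subset is not None:
        unknown = [i for i in subset if i not in ped]
        if unknown:
            raise PedigreeError(f"subset ids not in pedigree: {unknown[:5]}")
        idx = [ped.index(i) for i in subset]
        A = A[np.ix_(idx, idx)]
        ids = list(subset)
    return pd.DataFrame(A, index=ids, columns=ids)


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Per-animal inbreeding coefficient F_i = 0.5 * a(sire_i, dam_i).

    Founders and animals with any unknown parent get F = 0 (unknown parents
    are treated as unrelated founders).
    """
    A = _tabular_A(ped)
    return pd.Series(np.diag(A) - 1.0, index=ped.ids, name="F")


def mendelian_sampling_sd(ped: Pedigree, mode: str = "standard") -> pd.Series:
    """Per-animal Mendelian sampling standard deviation s_i.

    ``mode="standard"`` (default) is the decorrelated animal-model term:
    ``sqrt(0.5 - 0.25 (F_sire + F_dam))`` with two known parents,
    ``sqrt(0.75 - 0.25 F_parent)`` with one, and 1 for founders.

    ``mode="paper_literal"`` is ``sqrt(A_ii) = sqrt(1 + F_i)`` — the square
    root of the relationship-matrix diagonal.  The two definitions coincide
    only for founders; the standard one is what makes the gametic deviations
    z_i standard-normal a priori.
    """
    if mode not in ("standard", "paper_literal"):
        raise ValueError(f"unknown mode {mode!r}")
    F = inbreeding_coefficients(ped).to_numpy()
    if mode == "paper_literal":
        s = np.sqrt(1.0 + F)
    else:
        si, di = ped.sire_indices, ped.dam_indices
        s = np.ones(len(ped))
        both = (si >= 0) & (di >= 0)
        s[both] = np.sqrt(0.5 - 0.25 * (F[si[both]] + F[di[both]]))
        one_s = (si >= 0) & (di < 0)
        s[one_s] = np.sqrt(0.75 - 0.25 * F[si[one_s]])
        one_d = (si < 0) & (di >= 0)
        s[one_d] = np.sqrt(0.75 - 0.25 * F[di[one_d]])
    return pd.Series(s, index=ped.ids, name="mendelian_sd")
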