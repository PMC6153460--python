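"""Ternary compound x assay activity matrices.

High-throughput screening campaigns test overlapping compound collections
against panels of assays.  Organised as a matrix with compounds as rows and
assays as columns, every cell is in one of three states: the compound was
tested in the assay and called *active*, tested and called *inactive*, or
never tested.  The untested cells determine the sparseness of the matrix.

Untested cells are represented by absence, so memory scales with the number
of experimental observations rather than with rows x columns; real screening
matrices at this granularity are typically 10-25% dense over 1e4-1e6
compounds.  Identifiers are opaque strings (PubChem CIDs and AIDs in
practice) and never interpreted numerically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "Outcome",
    "Axis",
    "TernaryMatrix",
    "LineStats",
    "DegenerateMatrixError",
    "UnknownIdentifierError",
    "matrix_density",
    "activity_rate_among_tested",
    "active_cell_fraction",
    "line_stats",
    "subset",
]

# Internal sparse storage codes; 0 (structural absence) means untested.
_ACTIVE = 1
_INACTIVE = 2


class Outcome(enum.Enum):
    """Experimental call for one tested (compound, assay) pair."""

    ACTIVE = "active"
    INACTIVE = "inactive"


class Axis(enum.Enum):
    """Matrix axis: compounds are rows, assays are columns."""

    COMPOUND = "compound"
    ASSAY = "assay"


class DegenerateMatrixError(ValueError):
    """Operation requires a matrix with at least one row and one column."""


class UnknownIdentifierError(KeyError):
    """A compound or assay identifier is not present in the matrix."""

    def __str__(self) -> str:  # KeyError wraps its message in quotes
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class LineStats:
    """Density and activity statistics of a single row or column.

    ``density`` is the fraction of the line's cells that carry a test
    result; ``hit_rate`` is the fraction of tested cells called active,
    defined as 0 for a line with no tested cells (an untested line can then
    never be preferentially retained by activity weighting).
    """

    line_id: str
    axis: Axis
    n_tested: int
    n_active: int
    density: float
    hit_rate: float


def _as_code(value) -> int:
    if value is Outcome.ACTIVE or value == _ACTIVE:
        return _ACTIVE
    if value is Outcome.INACTIVE or value == _INACTIVE:
        return _INACTIVE
    raise ValueError(f"not a ternary cell value: {value!r}")


class TernaryMatrix:
    """Sparse compound (rows) x assay (columns) matrix of activity calls.

    Construct via :meth:`from_cells` (mapping of pairs to outcomes) or
    :meth:`from_coo` (index triplets); the plain constructor accepts a
    scipy sparse matrix of internal codes and is mostly for internal use.
    Matrices with zero rows or zero columns are permitted as explicit empty
    sentinels (the greedy extraction loop may legally empty a matrix), but
    the statistical operations below reject them.
    """

    __slots__ = ("compound_ids", "assay_ids", "_csr", "_cidx", "_aidx")

    def __init__(
        self,
        compound_ids: Iterable[str],
        assay_ids: Iterable[str],
        codes: sparse.spmatrix | None = None,
    ) -> None:
        self.compound_ids: tuple[str, ...] = tuple(str(c) for c in compound_ids)
        self.assay_ids: tuple[str, ...] = tuple(str(a) for a in assay_ids)
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound_ids")
        if len(set(self.assay_ids)) != len(self.assay_ids):
            raise ValueError("duplicate assay_ids")
        shape = (len(self.compound_ids), len(self.assay_ids))
        if codes is None:
            codes = sparse.csr_matrix(shape, dtype=np.int8)
        csr = sparse.csr_matrix(codes, dtype=np.int8, copy=True)
        if csr.shape != shape:
            raise ValueError(
                f"code matrix shape {csr.shape} does not match labels {shape}"
            )
        csr.eliminate_zeros()
        csr.sort_indices()
        if csr.nnz and not np.isin(csr.data, (_ACTIVE, _INACTIVE)).all():
            raise ValueError("cell codes must be ACTIVE or INACTIVE")
        self._csr = csr
        self._cidx = {c: i for i, c in enumerate(self.compound_ids)}
        self._aidx = {a: j for j, a in enumerate(self.assay_ids)}

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #

    @classmethod
    def from_cells(
        cls,
        compound_ids: Iterable[str],
        assay_ids: Iterable[str],
        cells: Mapping[tuple[str, str], Outcome],
    ) -> "TernaryMatrix":
        """Build from a ``{(compound_id, assay_id): Outcome}`` mapping."""
        compound_ids = tuple(str(c) for c in compound_ids)
        assay_ids = tuple(str(a) for a in assay_ids)
        cidx = {c: i for i, c in enumerate(compound_ids)}
        aidx = {a: j for j, a in enumerate(assay_ids)}
        rows, cols, data = [], [], []
        for (cid, aid), outcome in cells.items():
            if cid not in cidx:
                raise UnknownIdentifierError(f"unknown compound_id: {cid!r}")
            if aid not in aidx:
                raise UnknownIdentifierError(f"unknown assay_id: {aid!r}")
            rows.append(cidx[cid])
            cols.append(aidx[aid])
            data.append(_as_code(outcome))
        coo = sparse.coo_matrix(
            (np.asarray(data, dtype=np.int8), (rows, cols)),
            shape=(len(compound_ids), len(assay_ids)),
        )
        return cls(compound_ids, assay_ids, coo.tocsr())

    @classmethod
    def from_coo(
        cls,
        compound_ids: Iterable[str],
        assay_ids: Iterable[str],
        row_indices: np.ndarray,
        col_indices: np.ndarray,
        outcomes: np.ndarray,
    ) -> "TernaryMatrix":
        """Build from parallel index arrays.

        ``outcomes`` may hold :class:`Outcome` members or the integer codes
        1 (active) / 2 (inactive).  Duplicate (row, col) pairs are invalid.
        """
        compound_ids = tuple(str(c) for c in compound_ids)
        assay_ids = tuple(str(a) for a in assay_ids)
        out = np.asarray(
            [_as_code(v) for v in outcomes]
            if np.asarray(outcomes).dtype == object
            else outcomes,
            dtype=np.int8,
        )
        if out.size and not np.isin(out, (_ACTIVE, _INACTIVE)).all():
            raise ValueError("outcome codes must be 1 (active) or 2 (inactive)")
        rows = np.asarray(row_indices, dtype=np.int64)
        cols = np.asarray(col_indices, dtype=np.int64)
        shape = (len(compound_ids), len(assay_ids))
        flat = rows * shape[1] + cols
        if np.unique(flat).size != flat.size:
            raise ValueError("duplicate (compound, assay) pairs")
        coo = sparse.coo_matrix((out, (rows, cols)), shape=shape)
        return cls(compound_ids, assay_ids, coo.tocsr())

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_compounds, self.n_assays)

    @property
    def n_cells(self) -> int:
        """Number of tested cells (active + inactive)."""
        return int(self._csr.nnz)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self._csr.data == _ACTIVE))

    @property
    def is_empty(self) -> bool:
        """True for the degenerate sentinel (zero rows or zero columns)."""
        return self.n_compounds == 0 or self.n_assays == 0

    def compound_index(self, compound_id: str) -> int:
        try:
            return self._cidx[compound_id]
        except KeyError:
            raise UnknownIdentifierError(
                f"unknown compound_id: {compound_id!r}"
            ) from None

    def assay_index(self, assay_id: str) -> int:
        try:
            return self._aidx[assay_id]
        except KeyError:
            raise UnknownIdentifierError(f"unknown assay_id: {assay_id!r}") from None

    def get(self, compound_id: str, assay_id: str) -> Outcome | None:
        """Outcome of a pair, or None if untested."""
        code = self._csr[self.compound_index(compound_id), self.assay_index(assay_id)]
        if code == _ACTIVE:
            return Outcome.ACTIVE
        if code == _INACTIVE:
            return Outcome.INACTIVE
        return None

    def cells(self) -> Iterator[tuple[str, str, Outcome]]:
        """Iterate tested cells in row-major matrix order."""
        coo = self._csr.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield (
                self.compound_ids[i],
                self.assay_ids[j],
                Outcome.ACTIVE if v == _ACTIVE else Outcome.INACTIVE,
            )

    def to_dense_codes(self) -> np.ndarray:
        """Dense int8 array: 0 untested, 1 active, 2 inactive (small matrices)."""
        return np.asarray(self._csr.todense(), dtype=np.int8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TernaryMatrix):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.assay_ids == other.assay_ids
            and self._csr.shape == other._csr.shape
            and (self._csr != other._csr).nnz == 0
        )

    def __hash__(self):  # mutable-ish container semantics: identity hashing
        return id(self)

    def __repr__(self) -> str:
        return (
            f"TernaryMatrix({self.n_compounds} compounds x {self.n_assays} assays, "
            f"{self.n_cells} tested, {self.n_active} active)"
        )


def _require_nondegenerate(m: TernaryMatrix) -> None:
    if m.is_empty:
        raise DegenerateMatrixError(
            f"degenerate matrix with shape {m.shape}; operation undefined"
        )


def matrix_density(m: TernaryMatrix) -> float:
    """Fraction of cells carrying a test result: |cells| / (rows x cols)."""
    _require_nondegenerate(m)
    return m.n_cells / (m.n_compounds * m.n_assays)


def activity_rate_among_tested(m: TernaryMatrix) -> float:
    """Fraction of *tested* cells called active."""
    _require_nondegenerate(m)
    if m.n_cells == 0:
        raise DegenerateMatrixError("no tested cells; activity rate undefined")
    return m.n_active / m.n_cells


def active_cell_fraction(m: TernaryMatrix) -> float:
    """Fraction of *all* cells called active.

    Identity on counts: equals ``matrix_density * activity_rate_among_tested``
    because both reduce to n_active / (rows x cols).
    """
    _require_nondegenerate(m)
    return m.n_active / (m.n_compounds * m.n_assays)


def tested_counts(m: TernaryMatrix, axis: Axis) -> np.ndarray:
    """Per-line tested-cell counts along ``axis`` (vectorised)."""
    if axis is Axis.COMPOUND:
        return np.diff(m._csr.indptr)
    if axis is Axis.ASSAY:
        coo = m._csr.tocoo()
        return np.bincount(coo.col, minlength=m.n_assays)
    raise ValueError(f"invalid axis: {axis!r}")


def active_counts(m: TernaryMatrix, axis: Axis) -> np.ndarray:
    """Per-line active-cell counts along ``axis`` (vectorised)."""
    coo = m._csr.tocoo()
    mask = coo.data == _ACTIVE
    if axis is Axis.COMPOUND:
        return np.bincount(coo.row[mask], minlength=m.n_compounds)
    if axis is Axis.ASSAY:
        return np.bincount(coo.col[mask], minlength=m.n_assays)
    raise ValueError(f"invalid axis: {axis!r}")


def line_stats(m: TernaryMatrix, axis: Axis) -> list[LineStats]:
    """Per-line :class:`LineStats` along ``axis``, in matrix order."""
    _require_nondegenerate(m)
    if not isinstance(axis, Axis):
        raise ValueError(f"invalid axis: {axis!r}")
    tested = tested_counts(m, axis)
    active = active_counts(m, axis)
    ids = m.compound_ids if axis is Axis.COMPOUND else m.assay_ids
    length = m.n_assays if axis is Axis.COMPOUND else m.n_compounds
    out = []
    for line_id, n_t, n_a in zip(ids, tested, active):
        n_t = int(n_t)
        n_a = int(n_a)
        out.append(
            LineStats(
                line_id=line_id,
                axis=axis,
                n_tested=n_t,
                n_active=n_a,
                density=n_t / length,
                hit_rate=(n_a / n_t) if n_t else 0.0,
            )
        )
    return out


def subset(
    m: TernaryMatrix,
    keep_compounds: Iterable[str],
    keep_assays: Iterable[str],
) -> TernaryMatrix:
    """Restrict to the given identifier sets, preserving matrix order.

    Cell values are never created or mutated.  Unknown identifiers raise
    :class:`UnknownIdentifierError` naming the offender.  Empty keep sets
    yield the explicit empty-matrix sentinel rather than an error.
    """
    keep_c = set(keep_compounds)
    keep_a = set(keep_assays)
    for cid in keep_c:
        if cid not in m._cidx:
            raise UnknownIdentifierError(f"unknown compound_id: {cid!r}")
    for aid in keep_a:
        if aid not in m._aidx:
            raise UnknownIdentifierError(f"unknown assay_id: {aid!r}")
    rows = [i for i, c in enumerate(m.compound_ids) if c in keep_c]
    cols = [j for j, a in enumerate(m.assay_ids) if a in keep_a]
    sub = m._csr[rows][:, cols] if rows and cols else None
    return TernaryMatrix(
        [m.compound_ids[i] for i in rows],
        [m.assay_ids[j] for j in cols],
        sub,
    )
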