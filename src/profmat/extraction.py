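"""Greedy extraction of complete or dense profiling submatrices.

A variant of row/column-deletion biclustering: starting from a sparse
assay-compound matrix, the line (row or column) with the lowest weighted
density score is deleted repeatedly until the overall density of the
retained submatrix reaches a target ``tau``.  At ``tau = 1`` this yields a
complete profiling matrix in which every compound was tested in every
assay; at e.g. ``tau = 0.95`` a dense matrix with a small fraction of
untested cells.

Two weighting schemes steer the deletion order:

* axis weights ``assay_weight`` / ``compound_weight`` preferentially retain
  assays at the cost of compounds or vice versa;
* ``activity_weight`` preferentially retains lines rich in active calls
  (compounds with activity, assays with above-average hit rates), enriching
  active cells in the extracted submatrix.

The score of a line is ``axis_weight * (density + activity_weight *
hit_rate)``; at the defaults it reduces to the plain lowest-density rule.

Selection of the returned snapshot: every deletion strictly decreases
``rows x cols``, so the first snapshot whose density reaches ``tau`` is
also the unique maximal feasible snapshot along the trajectory.  Best-
snapshot tracking and first-hit stopping therefore provably coincide, and
both ``track_best`` settings stop at the first feasible snapshot.

Determinism: ties on the minimum score are broken by (1) deleting from the
axis with more lines, (2) the compound axis if the axes tie, (3) the
lexicographically smallest line identifier.  Identical input and
configuration give an identical trace on every platform.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    Axis,
    LineStats,
    TernaryMatrix,
    _ACTIVE,
    _require_nondegenerate,
    subset,
)

__all__ = [
    "ExtractionConfig",
    "RemovalStep",
    "ExtractionResult",
    "line_score",
    "extract_dense_submatrix",
    "select_assays_per_target",
    "brute_force_max_complete_submatrix",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the greedy deletion loop.

    target_density
        Stop threshold tau in (0, 1] on the overall density of the retained
        submatrix; 1.0 requests a complete matrix.
    assay_weight / compound_weight
        Nonnegative multipliers on column / row scores.  Raising
        ``assay_weight`` makes assays more expensive to delete, trading
        compounds for assay coverage.
    activity_weight
        Nonnegative bonus per unit hit rate, preferentially retaining lines
        with active calls.
    track_best
        Whether to select the best feasible snapshot over the trajectory
        rather than the first one; the two rules provably coincide (module
        docstring) and the flag is kept for config compatibility.
    """

    target_density: float = 1.0
    assay_weight: float = 1.0
    compound_weight: float = 1.0
    activity_weight: float = 0.0
    track_best: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.target_density <= 1.0):
            raise ValueError(f"target_density must be in (0, 1]: {self.target_density}")
        for name in ("assay_weight", "compound_weight", "activity_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0: {getattr(self, name)}")


@dataclass(frozen=True)
class RemovalStep:
    """One deletion of the greedy loop."""

    iteration: int
    axis: Axis
    line_id: str
    raw_density: float
    score: float
    density_after: float
    n_rows_after: int
    n_cols_after: int


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of :func:`extract_dense_submatrix`.

    ``feasible`` is False when the matrix was emptied before any snapshot
    reached the target density; the full trace is still returned so batch
    experiments over weight grids need not abort.
    """

    matrix: TernaryMatrix
    trace: tuple[RemovalStep, ...]
    achieved_density: float
    selected_iteration: int
    feasible: bool


def line_score(ls: LineStats, cfg: ExtractionConfig) -> float:
    """Weighted retention score of a line; the minimum-score line is deleted."""
    axis_weight = (
        cfg.compound_weight if ls.axis is Axis.COMPOUND else cfg.assay_weight
    )
    return axis_weight * (ls.density + cfg.activity_weight * ls.hit_rate)


def _lex_rank(ids: Sequence[str]) -> np.ndarray:
    """rank[i] = position of ids[i] in lexicographic order."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    rank = np.empty(len(ids), dtype=np.int64)
    for pos, i in enumerate(order):
        rank[i] = pos
    return rank


def extract_dense_submatrix(
    m: TernaryMatrix, cfg: ExtractionConfig | None = None
) -> ExtractionResult:
    """Run the greedy deletion loop until the density target is reached.

    The returned matrix is a subset of the input: identical cell values on
    the retained rows and columns, original order preserved.  Line
    statistics are maintained incrementally with exact integer counts, so
    the trajectory is identical to full recomputation at every iteration.
    """
    if cfg is None:
        cfg = ExtractionConfig()
    _require_nondegenerate(m)

    csr = m._csr
    csc = csr.tocsc()
    n_rows_total, n_cols_total = m.shape
    coo = csr.tocoo()
    act = coo.data == _ACTIVE
    row_tested = np.bincount(coo.row, minlength=n_rows_total)
    row_active = np.bincount(coo.row[act], minlength=n_rows_total)
    col_tested = np.bincount(coo.col, minlength=n_cols_total)
    col_active = np.bincount(coo.col[act], minlength=n_cols_total)

    row_alive = np.ones(n_rows_total, dtype=bool)
    col_alive = np.ones(n_cols_total, dtype=bool)
    row_rank = _lex_rank(m.compound_ids)
    col_rank = _lex_rank(m.assay_ids)

    n_r, n_c = n_rows_total, n_cols_total
    total = int(csr.nnz)
    w_c, w_a, w_act = cfg.compound_weight, cfg.assay_weight, cfg.activity_weight

    # Pre-pass: lines with zero tested cells can never belong to a tau > 0
    # snapshot; schedule them for deterministic early deletion (columns then
    # rows, lexicographic).  Later deletions may zero further lines; those
    # fall out of the main loop with score 0.
    pre: deque[tuple[Axis, int]] = deque()
    for j in sorted(np.flatnonzero(col_tested == 0), key=lambda j: m.assay_ids[j]):
        pre.append((Axis.ASSAY, int(j)))
    for i in sorted(np.flatnonzero(row_tested == 0), key=lambda i: m.compound_ids[i]):
        pre.append((Axis.COMPOUND, int(i)))

    trace: list[RemovalStep] = []
    feasible = False

    def pick_min_line() -> tuple[Axis, int, float]:
        ridx = np.flatnonzero(row_alive)
        cidx = np.flatnonzero(col_alive)
        rt = row_tested[ridx]
        ct = col_tested[cidx]
        r_density = rt / n_c
        c_density = ct / n_r
        if w_act:
            r_hr = np.where(rt > 0, row_active[ridx] / np.maximum(rt, 1), 0.0)
            c_hr = np.where(ct > 0, col_active[cidx] / np.maximum(ct, 1), 0.0)
            r_score = w_c * (r_density + w_act * r_hr)
            c_score = w_a * (c_density + w_act * c_hr)
        else:
            r_score = w_c * r_density
            c_score = w_a * c_density
        r_min = float(r_score.min())
        c_min = float(c_score.min())
        if r_min < c_min:
            axis = Axis.COMPOUND
        elif c_min < r_min:
            axis = Axis.ASSAY
        elif n_r > n_c:
            axis = Axis.COMPOUND
        elif n_c > n_r:
            axis = Axis.ASSAY
        else:
            axis = Axis.COMPOUND
        if axis is Axis.COMPOUND:
            tied = ridx[r_score == r_min]
            return axis, int(tied[np.argmin(row_rank[tied])]), r_min
        tied = cidx[c_score == c_min]
        return axis, int(tied[np.argmin(col_rank[tied])]), c_min

    while True:
        if n_r == 0 or n_c == 0:
            break  # emptied before reaching tau: infeasible
        density = total / (n_r * n_c)
        if density >= cfg.target_density:
            feasible = True
            break

        if pre:
            axis, idx = pre.popleft()
            score = 0.0
        else:
            axis, idx, score = pick_min_line()

        if axis is Axis.COMPOUND:
            raw_density = row_tested[idx] / n_c
            line_id = m.compound_ids[idx]
            row_alive[idx] = False
            n_r -= 1
            cells = slice(csr.indptr[idx], csr.indptr[idx + 1])
            cols = csr.indices[cells]
            vals = csr.data[cells]
            live = col_alive[cols]
            lcols = cols[live]
            col_tested[lcols] -= 1
            col_active[lcols[vals[live] == _ACTIVE]] -= 1
            total -= int(row_tested[idx])
        else:
            raw_density = col_tested[idx] / n_r
            line_id = m.assay_ids[idx]
            col_alive[idx] = False
            n_c -= 1
            cells = slice(csc.indptr[idx], csc.indptr[idx + 1])
            rows = csc.indices[cells]
            vals = csc.data[cells]
            live = row_alive[rows]
            lrows = rows[live]
            row_tested[lrows] -= 1
            row_active[lrows[vals[live] == _ACTIVE]] -= 1
            total -= int(col_tested[idx])

        density_after = total / (n_r * n_c) if n_r and n_c else 0.0
        trace.append(
            RemovalStep(
                iteration=len(trace) + 1,
                axis=axis,
                line_id=line_id,
                raw_density=float(raw_density),
                score=float(score),
                density_after=float(density_after),
                n_rows_after=n_r,
                n_cols_after=n_c,
            )
        )

    kept_compounds = [m.compound_ids[i] for i in np.flatnonzero(row_alive)]
    kept_assays = [m.assay_ids[j] for j in np.flatnonzero(col_alive)]
    result_matrix = subset(m, kept_compounds, kept_assays)
    achieved = total / (n_r * n_c) if feasible else 0.0
    return ExtractionResult(
        matrix=result_matrix,
        trace=tuple(trace),
        achieved_density=float(achieved),
        selected_iteration=len(trace),
        feasible=feasible,
    )


def select_assays_per_target(records: Sequence) -> list:
    """Keep one assay per target: the one with the most tested compounds.

    Selection is applied within each assay type independently (confirmatory
    and primary panels are built separately).  Ties are broken by the
    lexicographically smallest assay_id.  Output preserves the input order
    of the winning records.  Records must have unique ``assay_id``.
    """
    seen: set[str] = set()
    for r in records:
        if r.assay_id in seen:
            raise ValueError(f"duplicate assay_id: {r.assay_id!r}")
        seen.add(r.assay_id)
    best: dict[tuple[str, str], object] = {}
    for r in records:
        key = (r.assay_type, r.target_id)
        cur = best.get(key)
        if (
            cur is None
            or r.n_tested_compounds > cur.n_tested_compounds
            or (
                r.n_tested_compounds == cur.n_tested_compounds
                and r.assay_id < cur.assay_id
            )
        ):
            best[key] = r
    winners = set(id(r) for r in best.values())
    return [r for r in records if id(r) in winners]


def brute_force_max_complete_submatrix(
    m: TernaryMatrix, max_dim: int = 12
) -> tuple[tuple[str, ...], tuple[str, ...], int]:
    """Exhaustive maximum complete (fully tested) submatrix; test oracle.

    Enumerates every row subset; for each, the optimal column set is all
    columns fully tested on those rows.  Exponential in the number of rows,
    hence the ``max_dim`` cap.  Ties on cell count prefer more rows, then
    the lexicographically smallest sorted row-id tuple.  Returns (row ids,
    column ids, cell count) in matrix order.
    """
    _require_nondegenerate(m)
    n_r, n_c = m.shape
    if n_r > max_dim or n_c > max_dim:
        raise ValueError(
            f"matrix {m.shape} exceeds brute-force cap max_dim={max_dim}"
        )
    dense = m.to_dense_codes() != 0  # tested mask
    col_masks = [0] * n_c
    for j in range(n_c):
        mask = 0
        for i in range(n_r):
            if dense[i, j]:
                mask |= 1 << i
        col_masks[j] = mask

    best_cells = 0
    best_rows: tuple[int, ...] = ()
    best_cols: tuple[int, ...] = ()
    best_key: tuple[str, ...] = ()
    for s in range(1, 1 << n_r):
        rows = [i for i in range(n_r) if s >> i & 1]
        cols = [j for j in range(n_c) if col_masks[j] & s == s]
        cells = len(rows) * len(cols)
        if cells == 0:
            continue
        key = tuple(sorted(m.compound_ids[i] for i in rows))
        if (
            cells > best_cells
            or (cells == best_cells and len(rows) > len(best_rows))
            or (
                cells == best_cells
                and len(rows) == len(best_rows)
                and key < best_key
            )
        ):
            best_cells = cells
            best_rows = tuple(rows)
            best_cols = tuple(cols)
            best_key = key
    return (
        tuple(m.compound_ids[i] for i in best_rows),
        tuple(m.assay_ids[j] for j in best_cols),
        best_cells,
    )
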