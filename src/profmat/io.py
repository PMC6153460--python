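"""CSV formats for profiling matrices and assay metadata.

Three plain-text formats:

* **wide matrix CSV** — the deposition layout: compound identifiers in
  rows, assay identifiers in columns, cells ``1`` (active), ``0``
  (inactive) or ``NA`` (untested).  The first header cell is the literal
  label ``CID``.  Output is bit-exact and unquoted with ``\\n`` line
  endings, so files are byte-identical across platforms; identifiers must
  therefore be free of commas and newlines.
* **long sparse CSV** — one row per tested pair with columns
  ``compound_id, assay_id, outcome`` (``active``/``inactive``); untested
  pairs are simply absent.  The natural ingest format for raw screening
  outcomes.
* **assay table CSV** — assay/target metadata with columns
  ``assay_id, target_id, target_name, assay_type, n_tested_compounds``.
  ``target_name`` is free text, so this table goes through the stdlib csv
  module with minimal quoting.

The wide reader tolerates ``NA``, ``na`` and the empty string for untested
cells (deposition dialects differ) and rejects any other token with exact
coordinates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import Outcome, TernaryMatrix, _ACTIVE, _INACTIVE, _require_nondegenerate

__all__ = [
    "AssayRecord",
    "MatrixFormatError",
    "write_matrix_csv",
    "read_matrix_csv",
    "read_sparse_long_csv",
    "write_sparse_long_csv",
    "read_assay_table",
    "write_assay_table",
]

logger = logging.getLogger(__name__)

HEADER_LABEL = "CID"
UNTESTED_TOKENS = {"NA", "na", ""}
ASSAY_TABLE_HEADER = [
    "assay_id",
    "target_id",
    "target_name",
    "assay_type",
    "n_tested_compounds",
]
ASSAY_TYPES = {"confirmatory", "primary"}


class MatrixFormatError(ValueError):
    """Malformed matrix or table file; message carries line/coordinates."""


@dataclass(frozen=True)
class AssayRecord:
    """One assay with its target annotation and screening size."""

    assay_id: str
    target_id: str
    target_name: str
    assay_type: str
    n_tested_compounds: int

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(
                f"assay_type must be one of {sorted(ASSAY_TYPES)}: "
                f"{self.assay_type!r}"
            )
        if self.n_tested_compounds < 0:
            raise ValueError("n_tested_compounds must be >= 0")


def _check_identifier(kind: str, ident: str) -> None:
    if any(ch in ident for ch in ",\n\r"):
        raise MatrixFormatError(
            f"{kind} identifier contains a comma or newline: {ident!r}"
        )


def _sorted_view(m: TernaryMatrix) -> TernaryMatrix:
    rows = sorted(range(m.n_compounds), key=lambda i: m.compound_ids[i])
    cols = sorted(range(m.n_assays), key=lambda j: m.assay_ids[j])
    return TernaryMatrix(
        [m.compound_ids[i] for i in rows],
        [m.assay_ids[j] for j in cols],
        m._csr[rows][:, cols],
    )


def write_matrix_csv(m: TernaryMatrix, path: str | Path, sort: bool = False) -> None:
    """Write the wide 1/0/NA deposition format.

    ``sort=True`` emits rows and columns in lexicographic identifier order
    for canonical diffs; the default preserves in-memory order.
    """
    _require_nondegenerate(m)
    if sort:
        m = _sorted_view(m)
    for cid in m.compound_ids:
        _check_identifier("compound", cid)
    for aid in m.assay_ids:
        _check_identifier("assay", aid)
    tokens = {_ACTIVE: "1", _INACTIVE: "0"}
    with open(path, "w", newline="") as fh:
        fh.write(",".join([HEADER_LABEL, *m.assay_ids]) + "\n")
        csr = m._csr
        for i, cid in enumerate(m.compound_ids):
            row = ["NA"] * m.n_assays
            for j, v in zip(
                csr.indices[csr.indptr[i] : csr.indptr[i + 1]],
                csr.data[csr.indptr[i] : csr.indptr[i + 1]],
            ):
                row[j] = tokens[int(v)]
            fh.write(cid + "," + ",".join(row) + "\n")


def read_matrix_csv(path: str | Path) -> TernaryMatrix:
    """Read the wide 1/0/NA format; inverse of :func:`write_matrix_csv`."""
    with open(path, "r", newline="") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()  # trailing newline
    if not lines:
        raise MatrixFormatError(f"{path}: empty file, header expected")
    header = lines[0].split(",")
    assay_ids = header[1:]
    if len(set(assay_ids)) != len(assay_ids):
        raise MatrixFormatError(f"{path}: duplicate assay_id in header")
    n_assays = len(assay_ids)

    compound_ids: list[str] = []
    seen: set[str] = set()
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != n_assays + 1:
            raise MatrixFormatError(
                f"{path}: line {lineno}: expected {n_assays + 1} fields, "
                f"got {len(parts)}"
            )
        cid = parts[0]
        if cid in seen:
            raise MatrixFormatError(
                f"{path}: line {lineno}: duplicate compound_id {cid!r}"
            )
        seen.add(cid)
        i = len(compound_ids)
        compound_ids.append(cid)
        for j, tok in enumerate(parts[1:]):
            if tok == "1":
                code = _ACTIVE
            elif tok == "0":
                code = _INACTIVE
            elif tok in UNTESTED_TOKENS:
                continue
            else:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: invalid cell token {tok!r} at "
                    f"compound {cid!r}, assay {assay_ids[j]!r}"
                )
            rows.append(i)
            cols.append(j)
            data.append(code)
    return TernaryMatrix.from_coo(
        compound_ids,
        assay_ids,
        np.asarray(rows, dtype=np.int64),
        np.asarray(cols, dtype=np.int64),
        np.asarray(data, dtype=np.int8),
    )


def read_sparse_long_csv(path: str | Path) -> TernaryMatrix:
    """Read long-form tested pairs (compound_id, assay_id, outcome).

    Outcome tokens are case-insensitive ``active``/``inactive``.  Duplicate
    pairs with identical outcomes are deduplicated with a logged warning;
    conflicting duplicates are an error.  Row and column order follow first
    appearance.
    """
    with open(path, "r", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MatrixFormatError(f"{path}: empty file, header expected")
        reader.fieldnames = [f.strip() for f in reader.fieldnames]
        for required in ("compound_id", "assay_id", "outcome"):
            if required not in reader.fieldnames:
                raise MatrixFormatError(f"{path}: missing column {required!r}")
        cells: dict[tuple[str, str], int] = {}
        compound_order: list[str] = []
        assay_order: list[str] = []
        seen_c: set[str] = set()
        seen_a: set[str] = set()
        n_dups = 0
        for lineno, row in enumerate(reader, start=2):
            cid = (row["compound_id"] or "").strip()
            aid = (row["assay_id"] or "").strip()
            tok = (row["outcome"] or "").strip().lower()
            if tok == "active":
                code = _ACTIVE
            elif tok == "inactive":
                code = _INACTIVE
            else:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: unknown outcome token "
                    f"{row['outcome']!r}"
                )
            key = (cid, aid)
            if key in cells:
                if cells[key] != code:
                    raise MatrixFormatError(
                        f"{path}: line {lineno}: conflicting outcomes for "
                        f"pair ({cid!r}, {aid!r})"
                    )
                n_dups += 1
                continue
            cells[key] = code
            if cid not in seen_c:
                seen_c.add(cid)
                compound_order.append(cid)
            if aid not in seen_a:
                seen_a.add(aid)
                assay_order.append(aid)
    if n_dups:
        logger.warning(
            "%s: deduplicated %d repeated pair(s) with identical outcomes",
            path,
            n_dups,
        )
    cidx = {c: i for i, c in enumerate(compound_order)}
    aidx = {a: j for j, a in enumerate(assay_order)}
    rows = np.fromiter((cidx[c] for c, _ in cells), dtype=np.int64, count=len(cells))
    cols = np.fromiter((aidx[a] for _, a in cells), dtype=np.int64, count=len(cells))
    data = np.fromiter(cells.values(), dtype=np.int8, count=len(cells))
    return TernaryMatrix.from_coo(compound_order, assay_order, rows, cols, data)


def write_sparse_long_csv(
    m: TernaryMatrix, path: str | Path, sort: bool = False
) -> None:
    """Write tested pairs in long form, row-major matrix order."""
    _require_nondegenerate(m)
    if sort:
        m = _sorted_view(m)
    with open(path, "w", newline="") as fh:
        fh.write("compound_id,assay_id,outcome\n")
        for cid, aid, outcome in m.cells():
            fh.write(f"{cid},{aid},{outcome.value}\n")


def read_assay_table(path: str | Path) -> list[AssayRecord]:
    """Read assay/target metadata; duplicate assay_id is an error."""
    records: list[AssayRecord] = []
    seen: set[str] = set()
    with open(path, "r", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MatrixFormatError(f"{path}: empty file, header expected")
        missing = set(ASSAY_TABLE_HEADER) - set(reader.fieldnames)
        if missing:
            raise MatrixFormatError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            aid = row["assay_id"].strip()
            if aid in seen:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: duplicate assay_id {aid!r}"
                )
            seen.add(aid)
            try:
                records.append(
                    AssayRecord(
                        assay_id=aid,
                        target_id=row["target_id"].strip(),
                        target_name=(row["target_name"] or "").strip(),
                        assay_type=row["assay_type"].strip(),
                        n_tested_compounds=int(row["n_tested_compounds"]),
                    )
                )
            except ValueError as exc:
                raise MatrixFormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_assay_table(records: Iterable[AssayRecord], path: str | Path) -> None:
    """Write assay/target metadata; round-trip stable with the reader."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ASSAY_TABLE_HEADER)
        for r in records:
            writer.writerow(
                [r.assay_id, r.target_id, r.target_name, r.assay_type,
                 r.n_tested_compounds]
            )


def write_hit_rate_csv(m: TernaryMatrix, path: str | Path) -> None:
    """Per-assay hit-rate table: assay_id, n_tested, n_active, hit_rate."""
    from .core import Axis, line_stats

    with open(path, "w", newline="") as fh:
        fh.write("assay_id,n_tested,n_active,hit_rate\n")
        for ls in line_stats(m, Axis.ASSAY):
            fh.write(f"{ls.line_id},{ls.n_tested},{ls.n_active},{ls.hit_rate:.6g}\n")
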