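"""Delimited-table ingestion and emission.

All user-facing inputs are comma-separated text tables (RFC 4180), with or
without a header row.  Cells are kept verbatim as text — numeric parsing only
happens where an operation explicitly needs numbers — so that what is written
back out is byte-for-byte what was read in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "RawTable",
    "ColumnSelection",
    "TableFormatError",
    "read_table",
    "write_table",
    "preview",
    "extract_identifiers",
    "replicate_intersection_filter",
    "top_n_by_mean",
]


class TableFormatError(ValueError):
    """Raised for structurally unusable input tables."""


def _dedupe_headers(names: Sequence[str]) -> list[str]:
    # duplicate names get _2, _3, ... suffixes so columns stay addressable
    seen: dict[str, int] = {}
    out: list[str] = []
    for name in names:
        count = seen.get(name, 0) + 1
        seen[name] = count
        out.append(name if count == 1 else f"{name}_{count}")
    return out


@dataclass(frozen=True)
class RawTable:
    """An in-memory CSV: ordered headers plus rows of text cells.

    Invariants: every row has exactly ``len(headers)`` cells (short rows are
    padded with empty strings on read; longer rows are rejected), and headers
    are unique (duplicates deterministically suffixed).
    """

    headers: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        width = len(self.headers)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise TableFormatError(
                    f"row {i + 1} has {len(row)} cells, expected {width}"
                )
        if len(set(self.headers)) != width:
            raise TableFormatError("headers must be unique")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> int:
        try:
            return self.headers.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    def column(self, index: int) -> list[str]:
        return [row[index] for row in self.rows]


@dataclass(frozen=True)
class ColumnSelection:
    """One or more 0-based column positions of a :class:`RawTable`."""

    table: RawTable
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("at least one column must be selected")
        width = len(self.table.headers)
        bad = [i for i in self.indices if not 0 <= i < width]
        if bad:
            raise IndexError(f"column indices out of range: {bad} (table width {width})")


def read_table(path: str, has_header: bool) -> RawTable:
    """Read a comma-delimited text file into a :class:`RawTable`.

    When ``has_header`` is false, headers ``col_1 .. col_N`` are synthesized
    from the width of the first data row.  Rows shorter than the table width
    are padded with empty cells; longer rows are rejected.  A UTF-8 BOM is
    tolerated.
    """
    try:
        with open(path, "r", encoding="utf-8-sig", newline="") as fh:
            raw_rows = [list(row) for row in csv.reader(fh)]
    except FileNotFoundError:
        raise TableFormatError(f"no such file: {path}") from None
    raw_rows = [row for row in raw_rows if row]  # drop fully blank records
    if not raw_rows:
        raise TableFormatError(f"empty table: {path}")

    if has_header:
        headers = _dedupe_headers([cell.strip() for cell in raw_rows[0]])
        body = raw_rows[1:]
    else:
        headers = [f"col_{i + 1}" for i in range(len(raw_rows[0]))]
        body = raw_rows
    width = len(headers)

    rows: list[tuple[str, ...]] = []
    for i, row in enumerate(body):
        if len(row) > width:
            raise TableFormatError(
                f"{path}: row {i + 1} has {len(row)} cells, table width is {width}"
            )
        rows.append(tuple(row) + ("",) * (width - len(row)))
    return RawTable(headers=tuple(headers), rows=tuple(rows), source_path=path)


def write_table(table: RawTable, path: str) -> None:
    """Write a table as RFC 4180 CSV (no BOM, LF line endings)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(table.headers)
        writer.writerows(table.rows)


def preview(table: RawTable, n: int = 5) -> list[tuple[str, ...]]:
    """The first ``min(n, n_rows)`` rows, as a read-only snapshot."""
    if n < 1:
        raise ValueError("preview size must be >= 1")
    return list(table.rows[:n])


def extract_identifiers(sel: ColumnSelection) -> list[str]:
    """Cell values of the selected column(s), column-major, stripped, blanks dropped."""
    out: list[str] = []
    for idx in sel.indices:
        for row in sel.table.rows:
            cell = row[idx].strip()
            if cell:
                out.append(cell)
    if not out:
        names = ", ".join(sel.table.headers[i] for i in sel.indices)
        raise TableFormatError(f"selected column(s) contain no identifiers: {names}")
    return out


def replicate_intersection_filter(
    table: RawTable, replicate_cols: Sequence[int], id_col: int
) -> list[str]:
    """Identifiers present (non-empty cell) in *every* replicate column.

    Mirrors the screen-processing step of keeping only putative targets
    detected in all technical replicates.  Order of first occurrence is
    preserved; duplicate identifiers are emitted once.
    """
    if not replicate_cols:
        raise ValueError("no replicate columns given")
    ColumnSelection(table, tuple(replicate_cols) + (id_col,))  # validate indices
    seen: set[str] = set()
    out: list[str] = []
    for row in table.rows:
        ident = row[id_col].strip()
        if not ident or ident in seen:
            continue
        if all(row[c].strip() for c in replicate_cols):
            seen.add(ident)
            out.append(ident)
    return out


def top_n_by_mean(
    table: RawTable, value_cols: Sequence[int], id_col: int, n: int
) -> list[str]:
    """Identifiers of the ``n`` rows with the highest mean over ``value_cols``.

    The screen-processing "average signal across replicates, rank, take the
    top N" step.  Ties are broken by input row order (earlier row wins).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not value_cols:
        raise ValueError("no value columns given")
    ColumnSelection(table, tuple(value_cols) + (id_col,))
    scored: list[tuple[float, int, str]] = []
    for i, row in enumerate(table.rows):
        vals = []
        for c in value_cols:
            cell = row[c].strip()
            try:
                vals.append(float(cell))
            except ValueError:
                raise TableFormatError(
                    f"non-numeric value {cell!r} at row {i + 1}, "
                    f"column {table.headers[c]!r}"
                ) from None
        scored.append((sum(vals) / len(vals), i, row[id_col].strip()))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [ident for _, _, ident in scored[:n]]
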