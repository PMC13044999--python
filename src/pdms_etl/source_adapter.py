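"""Read-only access to the relational PDMS source.

All site-specific query plumbing lives behind this layer: connections are
opened strictly read-only (any write attempt raises), and identifier lists
are chunked into bounded batches before being interpolated into ``IN (…)``
clauses, so large cohorts never hit database parameter limits.  Results are
multiset-equal across chunk sizes.

The fixture backend is an embedded single-file SQLite database; porting to
another relational source means replacing this module only.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

from .errors import ReadOnlyViolationError, SchemaError, SourceConnectionError

DEFAULT_CHUNK_SIZE = 500  # safely below common relational parameter limits

__all__ = [
    "DEFAULT_CHUNK_SIZE",
    "SourceHandle",
    "QueryBatchPlan",
    "connect_readonly",
    "chunk_ids",
    "fetch_by_case_ids",
    "fetch_by_ids",
]


@dataclass
class SourceHandle:
    """Open read-only connection to the relational source."""

    uri: str
    dialect: str = "sqlite"
    read_only: bool = True
    _conn: Optional[sqlite3.Connection] = field(default=None, repr=False)

    def execute(self, sql: str, params: Sequence[Any] = ()) -> "list[dict]":
        """Run one statement, returning rows as dicts keyed by source column names."""
        if self._conn is None:
            raise SourceConnectionError("handle is closed")
        try:
            cursor = self._conn.execute(sql, tuple(params))
        except sqlite3.OperationalError as exc:
            message = str(exc)
            if "readonly" in message or "read-only" in message:
                raise ReadOnlyViolationError(
                    f"write attempted through read-only handle: {message}"
                ) from exc
            if "no such table" in message or "no such column" in message:
                raise SchemaError(message) from exc
            raise
        if cursor.description is None:
            return []
        columns = [d[0] for d in cursor.description]
        return [dict(zip(columns, row)) for row in cursor.fetchall()]

    def table_names(self) -> "set[str]":
        rows = self.execute("SELECT name FROM sqlite_master WHERE type='table'")
        return {r["name"] for r in rows}

    def table_columns(self, table: str) -> "list[str]":
        if table not in self.table_names():
            raise SchemaError(f"no such table: {table!r}")
        return [r["name"] for r in self.execute(f"PRAGMA table_info({table})")]

    def close(self) -> None:
        if self._conn is not None:
            self._conn.close()
            self._conn = None

    def __enter__(self) -> "SourceHandle":
        return self

    def __exit__(self, *exc_info: Any) -> None:
        self.close()


def connect_readonly(uri: "str | Path") -> SourceHandle:
    """Open a read-only handle on an embedded relational database file.

    The read-only guarantee is enforced by the engine itself (SQLite
    ``mode=ro``), not by convention: INSERT/UPDATE/DELETE raise
    :class:`ReadOnlyViolationError`.
    """
    path = Path(str(uri))
    if not path.exists():
        raise SourceConnectionError(f"source not found: {path}")
    try:
        conn = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
        conn.execute("SELECT 1")
    except sqlite3.Error as exc:
        raise SourceConnectionError(f"cannot open source {path}: {exc}") from exc
    return SourceHandle(uri=str(path), _conn=conn)


@dataclass(frozen=True)
class QueryBatchPlan:
    """Order-preserving partition of an identifier list into bounded chunks."""

    chunk_size: int
    chunks: "tuple[tuple[Any, ...], ...]"

    @property
    def n_ids(self) -> int:
        return sum(len(c) for c in self.chunks)


def chunk_ids(ids: Sequence[Any], chunk_size: int) -> QueryBatchPlan:
    """Partition ``ids`` into consecutive chunks of at most ``chunk_size``.

    Concatenating the chunks reproduces the input exactly; no chunk is empty
    unless the input is empty.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    ids = list(ids)
    chunks = tuple(
        tuple(ids[i : i + chunk_size]) for i in range(0, len(ids), chunk_size)
    )
    return QueryBatchPlan(chunk_size=chunk_size, chunks=chunks)


def fetch_by_ids(
    handle: SourceHandle,
    table: str,
    key_column: str,
    ids: Sequence[Any],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> "list[dict]":
    """Fetch all rows of ``table`` whose ``key_column`` is in ``ids``, chunked.

    Identifiers are deduplicated (set semantics, first occurrence order) before
    chunking, so a duplicated request id never double-counts source rows.  The
    returned row multiset is independent of ``chunk_size``.
    """
    if table not in handle.table_names():
        raise SchemaError(f"no such table: {table!r}")
    if key_column not in handle.table_columns(table):
        raise SchemaError(f"table {table!r} has no column {key_column!r}")
    deduped = list(dict.fromkeys(ids))
    rows: list[dict] = []
    for chunk in chunk_ids(deduped, chunk_size).chunks:
        placeholders = ",".join("?" * len(chunk))
        rows.extend(
            handle.execute(
                f"SELECT * FROM {table} WHERE {key_column} IN ({placeholders})",
                chunk,
            )
        )
    return rows


def fetch_by_case_ids(
    handle: SourceHandle,
    table: str,
    case_ids: Sequence[Any],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> "list[dict]":
    """Case-keyed fetch — extractions are tied to case numbers throughout."""
    return fetch_by_ids(handle, table, "case_id", case_ids, chunk_size)
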