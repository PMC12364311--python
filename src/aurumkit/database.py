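"""The on-disk relational store.

Raw extracts are far too large to hold in memory, so medical-event data for
the cohort is bulk-loaded into a single-file SQLite database and all
downstream variable extraction runs as queries against it.  Tables are keyed
by name only — no constraints, no indexes by default — so appends stay
cheap; dates are stored as ISO-8601 text, which sorts lexicographically in
chronological order.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .config import DEFAULT_SETTINGS, Settings, logger
from .raw_io import (
    FilenameParseError,
    iter_raw_file,
    parse_filename,
    scan_directory,
)

__all__ = [
    "StoreHandle",
    "SubsetSpec",
    "connect",
    "close",
    "list_tables",
    "add_to_database",
    "cprd_extract",
    "build_index",
]


class StoreClosedError(RuntimeError):
    """Operation attempted on a closed store handle."""


@dataclass
class StoreHandle:
    """An open connection to the SQLite store."""

    db_path: Path
    _conn: sqlite3.Connection | None

    @property
    def open(self) -> bool:
        return self._conn is not None

    @property
    def conn(self) -> sqlite3.Connection:
        if self._conn is None:
            raise StoreClosedError(f"store handle to {self.db_path} is closed")
        return self._conn

    def close(self) -> None:
        if self._conn is not None:
            self._conn.close()
            self._conn = None

    def __enter__(self) -> "StoreHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def connect(db_path: str | Path) -> StoreHandle:
    """Open (creating if absent) the SQLite store at *db_path*."""
    db_path = Path(db_path)
    if not db_path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {db_path.parent}")
    conn = sqlite3.connect(db_path)
    return StoreHandle(db_path, conn)


def close(handle: StoreHandle) -> None:
    """Close the store connection; closing twice is a no-op."""
    handle.close()


def list_tables(handle: StoreHandle) -> list[str]:
    cur = handle.conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
    )
    return [row[0] for row in cur.fetchall()]


# ---------------------------------------------------------------------------
# Subset specification
# ---------------------------------------------------------------------------

class SubsetSpec:
    """Which patients to keep at ingest time.

    Two forms exist: a plain set of patient IDs, or (patid, set) pairs.  In
    pair form, a file whose name parses to set X is filtered only against
    the patids assigned to set X — a much smaller membership test when the
    cohort is large, exploiting the guarantee that a patient's medical-event
    files carry the same set token as their patient file.
    """

    def __init__(
        self,
        ids: Iterable[str] | None = None,
        pairs: pd.DataFrame | None = None,
    ) -> None:
        if (ids is None) == (pairs is None):
            raise ValueError("give exactly one of ids or pairs")
        self.ids: frozenset[str] | None = None
        self.by_set: dict[int, frozenset[str]] | None = None
        if ids is not None:
            self.ids = frozenset(str(p) for p in ids)
        else:
            if not {"patid", "set"} <= set(pairs.columns):
                raise ValueError("pair-form subset needs 'patid' and 'set' columns")
            pairs = pairs[["patid", "set"]].astype({"patid": str})
            if pairs["patid"].duplicated().any():
                raise ValueError("pair-form subset maps a patid to more than one set")
            self.by_set = {
                int(s): frozenset(g["patid"]) for s, g in pairs.groupby("set")
            }

    @classmethod
    def coerce(cls, obj) -> "SubsetSpec":
        if isinstance(obj, cls):
            return obj
        if isinstance(obj, pd.DataFrame):
            return cls(pairs=obj)
        return cls(ids=obj)

    def patids_for(self, set_number: int | None) -> frozenset[str]:
        if self.ids is not None:
            return self.ids
        assert self.by_set is not None
        if set_number is None:
            raise ValueError(
                "pair-form subset requires a filename with a parseable set token"
            )
        return self.by_set.get(set_number, frozenset())


# ---------------------------------------------------------------------------
# Ingest
# ---------------------------------------------------------------------------

def _table_columns(handle: StoreHandle, table: str) -> list[str] | None:
    cur = handle.conn.execute("SELECT name FROM sqlite_master WHERE type='table' AND name=?", (table,))
    if cur.fetchone() is None:
        return None
    return [r[1] for r in handle.conn.execute(f'PRAGMA table_info("{table}")')]


def _to_storable(chunk: pd.DataFrame) -> pd.DataFrame:
    out = chunk.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def add_to_database(
    handle: StoreHandle,
    filepath: str | Path,
    filetype: str | None = None,
    subset_patids: SubsetSpec | pd.DataFrame | Iterable[str] | None = None,
    mode: str = "append",
    table_name: str | None = None,
    reader_override: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> int:
    """Stream one raw file into the store; returns rows added.

    ``mode='overwrite'`` replaces the target table, ``'append'`` extends it
    (the table must already exist and have the same columns).  The table is
    named *table_name*, defaulting to the filetype.  With a subset, only
    rows whose patid passes the filter are stored.
    """
    filepath = Path(filepath)
    if mode not in ("overwrite", "append"):
        raise ValueError("mode must be 'overwrite' or 'append'")
    if filetype is None and reader_override is None:
        try:
            filetype = parse_filename(filepath.name).filetype
        except FilenameParseError:
            raise ValueError(
                f"cannot infer filetype for {filepath.name!r}; pass filetype="
            ) from None
    table = table_name or filetype
    if table is None:
        raise ValueError("table_name required when filetype is unknown")

    subset = None if subset_patids is None else SubsetSpec.coerce(subset_patids)
    wanted: frozenset[str] | None = None
    if subset is not None:
        try:
            set_number: int | None = parse_filename(filepath.name).set_number
        except FilenameParseError:
            set_number = None
        wanted = subset.patids_for(set_number)

    existing = _table_columns(handle, table)
    if mode == "append" and existing is None:
        raise ValueError(
            f"table {table!r} does not exist; ingest the first file with "
            "mode='overwrite'"
        )

    total = 0
    first = True
    for chunk in iter_raw_file(
        filepath, filetype=filetype, reader_override=reader_override, settings=settings
    ):
        if wanted is not None:
            chunk = chunk[chunk["patid"].isin(wanted)]
        chunk = _to_storable(chunk)
        if first and mode == "overwrite":
            handle.conn.execute(f'DROP TABLE IF EXISTS "{table}"')
            existing = None
        if existing is not None and list(chunk.columns) != existing:
            raise ValueError(
                f"column mismatch appending {filepath.name} to table {table!r}: "
                f"file has {list(chunk.columns)}, table has {existing}"
            )
        chunk.to_sql(table, handle.conn, if_exists="append", index=False)
        existing = existing or list(chunk.columns)
        total += len(chunk)
        first = False
    if first and mode == "overwrite":
        # Empty file: still (re)create the table from the header.
        header = pd.read_csv(filepath, sep=settings.delimiter, nrows=0, dtype=str)
        handle.conn.execute(f'DROP TABLE IF EXISTS "{table}"')
        header.to_sql(table, handle.conn, if_exists="replace", index=False)
    handle.conn.commit()
    logger.info("added %d rows from %s to table %r", total, filepath.name, table)
    return total


def _deduplicate(handle: StoreHandle, table: str) -> int:
    """Remove exact-duplicate rows (equality on all stored columns)."""
    cols = _table_columns(handle, table)
    if not cols:
        return 0
    col_list = ", ".join(f'"{c}"' for c in cols)
    cur = handle.conn.execute(
        f'DELETE FROM "{table}" WHERE rowid NOT IN '
        f'(SELECT MIN(rowid) FROM "{table}" GROUP BY {col_list})'
    )
    handle.conn.commit()
    return cur.rowcount


def cprd_extract(
    handle: StoreHandle,
    filepath: str | Path,
    filetype: str,
    subset_patids: SubsetSpec | pd.DataFrame | Iterable[str] | None = None,
    str_match: str | None = None,
    table_name: str | None = None,
    rm_duplicates: bool = False,
    reader_override: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> int:
    """Ingest every matching file in a directory; returns total rows stored.

    Files whose names contain *str_match* (default: the filetype, with
    ``drug_issue`` accepted for ``drugissue``) are ingested in deterministic
    (set, part, name) order — the first with overwrite, the rest appended —
    so re-running the extract reproduces the table exactly.  With
    ``rm_duplicates=True``, exact-duplicate rows are removed across the
    whole extract after loading.
    """
    filepath = Path(filepath)
    if not filepath.is_dir():
        raise FileNotFoundError(f"not a directory: {filepath}")
    paths = scan_directory(filepath, str_match or filetype)
    if not paths:
        raise FileNotFoundError(
            f"no files matching {str_match or filetype!r} in {filepath}"
        )
    table = table_name or filetype
    total = 0
    for i, path in enumerate(paths):
        total += add_to_database(
            handle,
            path,
            filetype=filetype,
            subset_patids=subset_patids,
            mode="overwrite" if i == 0 else "append",
            table_name=table,
            reader_override=reader_override,
            settings=settings,
        )
    if rm_duplicates:
        removed = _deduplicate(handle, table)
        total -= removed
        logger.info("removed %d duplicate rows from table %r", removed, table)
    return total


def build_index(handle: StoreHandle, table: str, code_column: str) -> None:
    """Optionally index (patid, code) after load.

    The store is deliberately unindexed by default — bulk loads stay cheap
    and queries scan linearly — but for repeated querying of a large table
    an index can pay for itself.
    """
    handle.conn.execute(
        f'CREATE INDEX IF NOT EXISTS "idx_{table}_patid_code" '
        f'ON "{table}" (patid, "{code_column}")'
    )
    handle.conn.commit()
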