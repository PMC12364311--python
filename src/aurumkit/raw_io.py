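"""Reading raw CPRD-Aurum-dialect extract files.

Raw extracts arrive as thousands of tab-delimited ``.txt`` files named

    ``<prefix>_setX_extract_<filetype>_0Y.txt``

where ``setX`` partitions patients into batches and ``0Y`` numbers the parts
of each file type within a batch.  This module parses that naming convention
and reads each file type into a typed :class:`pandas.DataFrame` with dates
parsed and identifier columns held as text (Aurum identifiers exceed 2**53,
so integer storage would silently lose precision).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SETTINGS, Settings, logger

__all__ = [
    "FILETYPES",
    "RawFileName",
    "FilenameParseError",
    "SchemaError",
    "parse_filename",
    "format_filename",
    "scan_directory",
    "read_raw_file",
    "iter_raw_file",
    "write_raw_file",
]

#: Recognised file types, longest first so substring matching is unambiguous.
FILETYPES = (
    "consultation",
    "observation",
    "hes_primary",
    "drugissue",
    "referral",
    "problem",
    "patient",
    "death",
)

#: Alternate spellings accepted when matching file types inside filenames.
_FILETYPE_ALIASES = {"drugissue": ("drugissue", "drug_issue")}

#: Mandatory columns per file type; missing ones raise :class:`SchemaError`.
MANDATORY_COLUMNS = {
    "patient": ("patid",),
    "observation": ("patid", "medcodeid", "obsdate"),
    "drugissue": ("patid", "prodcodeid", "issuedate"),
    "referral": ("patid",),
    "problem": ("patid",),
    "consultation": ("patid",),
    "hes_primary": ("patid", "ICD10"),
    "death": ("patid",),
}

#: Columns parsed as calendar dates per file type.  referral/problem/
#: consultation columns are not fixed by the source specification, so their
#: date-column lists are configurable via ``date_columns``.
DATE_COLUMNS = {
    "patient": ("regstartdate", "regenddate", "cprd_ddate", "emis_ddate"),
    "observation": ("obsdate",),
    "drugissue": ("issuedate",),
    "referral": ("obsdate",),
    "problem": ("obsdate",),
    "consultation": ("consdate",),
    "hes_primary": ("admidate", "discharged"),
    "death": ("dod", "dor"),
}

#: Columns coerced to numeric (others stay text).
NUMERIC_COLUMNS = {
    "patient": ("gender", "yob"),
    "observation": ("value",),
}


class FilenameParseError(ValueError):
    """Filename does not follow the extract naming convention."""


class SchemaError(ValueError):
    """A raw file is missing a mandatory column."""


@dataclass(frozen=True)
class RawFileName:
    """Parsed components of an extract filename."""

    prefix: str
    set_number: int
    filetype: str
    part_number: int | None = None

    def format(self, pad: int = 3) -> str:
        return format_filename(
            self.prefix, self.set_number, self.filetype, self.part_number, pad=pad
        )


_SET_RE = re.compile(r"set(\d+)", re.IGNORECASE)
_PART_RE = re.compile(r"_(\d+)\.txt$", re.IGNORECASE)


def parse_filename(name: str) -> RawFileName:
    """Parse a bare extract filename into its components.

    The set number is taken from the first ``set<digits>`` token, the file
    type by case-insensitive substring match, and the part number from a
    trailing ``_<digits>.txt`` (any digit width: both ``_01`` and ``_001``
    occur in practice).
    """
    base = Path(name).name
    m_set = _SET_RE.search(base)
    if m_set is None:
        raise FilenameParseError(f"no 'set<digits>' token in filename: {base!r}")
    filetype = match_filetype(base)
    if filetype is None:
        raise FilenameParseError(f"no recognizable filetype in filename: {base!r}")
    m_part = _PART_RE.search(base)
    part = int(m_part.group(1)) if m_part else None
    prefix = base[: m_set.start()].rstrip("_")
    return RawFileName(prefix, int(m_set.group(1)), filetype, part)


def format_filename(
    prefix: str,
    set_number: int,
    filetype: str,
    part_number: int | None = None,
    pad: int = 3,
) -> str:
    """Inverse of :func:`parse_filename` for the set/filetype/part fields."""
    part = "" if part_number is None else f"_{part_number:0{pad}d}"
    return f"{prefix}_set{set_number}_extract_{filetype}{part}.txt"


def match_filetype(name: str) -> str | None:
    """Case-insensitive substring match of a known filetype within *name*."""
    low = name.lower()
    for ft in FILETYPES:
        for alias in _FILETYPE_ALIASES.get(ft, (ft,)):
            if alias in low:
                return ft
    return None


def scan_directory(
    directory: str | Path, match: str, filetype_alias: bool = True
) -> list[Path]:
    """List ``.txt`` files in *directory* containing *match* (case-insensitive).

    Returns paths sorted by (set, part, name) so ingest order is
    deterministic; files that do not parse sort after those that do.
    """
    directory = Path(directory)
    needles = [match.lower()]
    if filetype_alias:
        needles = [a for a in _FILETYPE_ALIASES.get(match.lower(), needles)]

    def _key(p: Path):
        try:
            parsed = parse_filename(p.name)
            return (0, parsed.set_number, parsed.part_number or 0, p.name)
        except FilenameParseError:
            return (1, 0, 0, p.name)

    hits = [
        p
        for p in directory.iterdir()
        if p.suffix.lower() == ".txt" and any(n in p.name.lower() for n in needles)
    ]
    return sorted(hits, key=_key)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_date_column(col: pd.Series, settings: Settings) -> tuple[pd.Series, int]:
    """Parse a text column to dates; unparseable cells become missing."""
    col = col.astype("string")
    out = pd.Series(pd.NaT, index=col.index, dtype="datetime64[ns]")
    remaining = col.notna() & (col.str.strip() != "")
    for fmt in settings.date_formats:
        if not remaining.any():
            break
        parsed = pd.to_datetime(col[remaining], format=fmt, errors="coerce")
        out.loc[remaining] = parsed
        remaining = remaining & parsed.isna().reindex(col.index, fill_value=False)
    n_bad = int(remaining.sum())
    return out, n_bad


def _type_chunk(
    chunk: pd.DataFrame,
    filetype: str,
    date_columns: Sequence[str],
    settings: Settings,
    source: str,
) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS.get(filetype, ()) if c not in chunk.columns]
    if missing:
        raise SchemaError(
            f"{source}: missing mandatory column(s) {missing} for filetype "
            f"{filetype!r}; found {list(chunk.columns)}"
        )
    for col in date_columns:
        if col in chunk.columns:
            parsed, n_bad = _parse_date_column(chunk[col], settings)
            if n_bad:
                logger.warning(
                    "%s: %d unparseable date(s) in column %r set to missing",
                    source, n_bad, col,
                )
            chunk[col] = parsed
    for col in NUMERIC_COLUMNS.get(filetype, ()):
        if col in chunk.columns:
            chunk[col] = pd.to_numeric(chunk[col], errors="coerce")
    return chunk


def iter_raw_file(
    path: str | Path,
    filetype: str | None = None,
    reader_override: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    delimiter: str | None = None,
    date_columns: Sequence[str] | None = None,
    chunk_size: int | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> Iterator[pd.DataFrame]:
    """Stream a raw extract file in typed chunks.

    Every column is read as text and only the known date/numeric columns are
    converted, so unknown columns pass through verbatim.  ``reader_override``
    is applied to each typed chunk, letting callers re-shape arbitrary files.
    """
    path = Path(path)
    if filetype is None:
        filetype = match_filetype(path.name)
    if filetype is None and reader_override is None:
        raise ValueError(
            f"cannot infer filetype from {path.name!r}; pass filetype= or "
            "reader_override="
        )
    if date_columns is None:
        date_columns = DATE_COLUMNS.get(filetype or "", ())
    delimiter = settings.delimiter if delimiter is None else delimiter
    chunk_size = settings.chunk_size if chunk_size is None else chunk_size

    with pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        na_values=[""],
        chunksize=chunk_size,
    ) as reader:
        for chunk in reader:
            chunk = _type_chunk(chunk, filetype or "", date_columns, settings, path.name)
            if reader_override is not None:
                chunk = reader_override(chunk)
            yield chunk


def read_raw_file(
    path: str | Path,
    filetype: str | None = None,
    reader_override: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    delimiter: str | None = None,
    date_columns: Sequence[str] | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Read a whole raw extract file into one typed table."""
    chunks = list(
        iter_raw_file(
            path,
            filetype=filetype,
            reader_override=reader_override,
            delimiter=delimiter,
            date_columns=date_columns,
            settings=settings,
        )
    )
    if len(chunks) == 1:
        return chunks[0].reset_index(drop=True)
    return pd.concat(chunks, ignore_index=True)


def write_raw_file(
    table: pd.DataFrame,
    path: str | Path,
    delimiter: str | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> None:
    """Write a table back to delimited text, dates in the output format."""
    delimiter = settings.delimiter if delimiter is None else delimiter
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(settings.date_output_format)
    out.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
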