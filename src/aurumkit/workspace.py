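"""The project-directory convention layer.

A standard tree lets stores and codelists be referred to by name instead of
by path, which keeps analysis scripts portable between machines:

    <root>/
      data/extraction/      extracted variables land here
      data/sql/             SQLite stores, referable as <name>.sqlite
      codelists/analysis/   codelists, referable as <name>.csv

``root`` defaults to the current working directory.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from . import database
from .query import Codelist

__all__ = [
    "WorkspaceLayout",
    "create_directory_system",
    "resolve_codelist",
    "resolve_store",
    "save_variable",
    "load_variable",
    "variable_filename",
]


@dataclass(frozen=True)
class WorkspaceLayout:
    root: Path

    @property
    def extraction_dir(self) -> Path:
        return self.root / "data" / "extraction"

    @property
    def sql_dir(self) -> Path:
        return self.root / "data" / "sql"

    @property
    def codelist_dir(self) -> Path:
        return self.root / "codelists" / "analysis"


def _layout(layout: WorkspaceLayout | str | Path | None) -> WorkspaceLayout:
    if isinstance(layout, WorkspaceLayout):
        return layout
    return WorkspaceLayout(Path(layout) if layout is not None else Path.cwd())


def create_directory_system(root: str | Path | None = None) -> WorkspaceLayout:
    """Create the standard tree under *root*; idempotent, never deletes."""
    layout = _layout(root)
    for d in (layout.extraction_dir, layout.sql_dir, layout.codelist_dir):
        d.mkdir(parents=True, exist_ok=True)
    return layout


def resolve_codelist(
    codelist_vector: Iterable[str] | None = None,
    codelist_name: str | None = None,
    codelist_table: Codelist | pd.DataFrame | None = None,
    layout: WorkspaceLayout | str | Path | None = None,
    code_kind: str = "medcodeid",
) -> Codelist:
    """Resolve a codelist from whichever source is given.

    Precedence when several are supplied: explicit vector of codes, then
    in-memory table, then name (loaded from
    ``<root>/codelists/analysis/<name>.csv``).
    """
    if codelist_vector is not None:
        return Codelist.from_vector(codelist_vector, code_kind)
    if codelist_table is not None:
        return Codelist.coerce(codelist_table)
    if codelist_name is not None:
        path = _layout(layout).codelist_dir / f"{codelist_name}.csv"
        if not path.is_file():
            raise FileNotFoundError(f"no codelist at {path}")
        return Codelist.from_csv(path)
    raise ValueError("no codelist given (vector, table or name)")


@contextlib.contextmanager
def resolve_store(
    store: database.StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    layout: WorkspaceLayout | str | Path | None = None,
) -> Iterator[database.StoreHandle]:
    """Yield an open store handle, closing it on exit only if opened here.

    Exactly one of *store* (an already-open handle, passed through and left
    open), *db_name* (resolved to ``<root>/data/sql/<name>.sqlite``) or
    *db_filepath* must be given.
    """
    given = [store is not None, db_name is not None, db_filepath is not None]
    if sum(given) != 1:
        raise ValueError("give exactly one of store, db_name or db_filepath")
    if store is not None:
        yield store
        return
    if db_name is not None:
        db_filepath = _layout(layout).sql_dir / f"{db_name}.sqlite"
    db_filepath = Path(db_filepath)
    if not db_filepath.is_file():
        raise FileNotFoundError(f"no store at {db_filepath}")
    handle = database.connect(db_filepath)
    try:
        yield handle
    finally:
        handle.close()


def variable_filename(varname: str, t_offset: int = 0) -> str:
    """``var_<varname>.csv``, with ``_t<offset>`` appended when nonzero."""
    suffix = f"_t{t_offset}" if t_offset else ""
    return f"var_{varname}{suffix}.csv"


def save_variable(
    result: pd.DataFrame,
    varname: str,
    t_offset: int = 0,
    out_filepath: str | Path | None = None,
    layout: WorkspaceLayout | str | Path | None = None,
) -> Path:
    """Write an extracted variable table to disk and return the path.

    Without *out_filepath* the file goes to ``data/extraction/`` under the
    workspace root, named by :func:`variable_filename`.
    """
    if out_filepath is None:
        lay = _layout(layout)
        if not lay.extraction_dir.is_dir():
            raise FileNotFoundError(
                f"{lay.extraction_dir} does not exist; run create_directory_system "
                "or pass out_filepath"
            )
        out_filepath = lay.extraction_dir / variable_filename(varname, t_offset)
    out_filepath = Path(out_filepath)
    out = result.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(out_filepath, index=False, lineterminator="\n")
    return out_filepath


def load_variable(path: str | Path) -> pd.DataFrame:
    """Reload a saved variable table (IDs as text, dates parsed)."""
    out = pd.read_csv(path, dtype={"patid": str})
    for col in out.columns:
        if col.endswith("date") or col in ("obsdate", "issuedate"):
            out[col] = pd.to_datetime(out[col], format="%Y-%m-%d", errors="coerce")
    return out
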