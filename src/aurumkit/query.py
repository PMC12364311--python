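"""Codelist-driven queries and their merge-with-cohort combinators.

The unit of phenotyping is the *codelist*: a curated set of codes denoting
one clinical concept (``medcodeid`` for medical observations,
``prodcodeid`` for prescriptions, ``ICD10`` for linked hospital diagnoses).
:func:`db_query` pulls every stored record whose code is in a codelist;
:func:`combine_query` and :func:`combine_query_boolean` then merge a query
with a cohort and apply index-date-relative window, bound and count rules.
These are the building blocks the named variable extractors are made of.

:func:`brute_force_history` is the independent oracle: a deliberate
for-loop over the raw text files, never touching the store, against which
the store-backed path can be checked patient-by-patient.

Window convention, applied identically everywhere: the event window is
``[indexdt + t_offset - time_prev, indexdt + t_offset + time_post]`` with
both endpoints inclusive, and "history" means an event dated on or before
the (offset) index date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import validate_cohort
from .config import DEFAULT_SETTINGS, Settings, logger
from .database import StoreHandle, _table_columns
from .raw_io import scan_directory

__all__ = [
    "Codelist",
    "db_query",
    "combine_query",
    "combine_query_boolean",
    "brute_force_history",
]

CODE_KINDS = ("medcodeid", "prodcodeid", "ICD10")

#: Event-date column per code kind's home table.
_DATE_FOR_KIND = {"medcodeid": "obsdate", "prodcodeid": "issuedate", "ICD10": "admidate"}


@dataclass(frozen=True)
class Codelist:
    """A set of codes denoting one clinical concept, plus annotations.

    ``table`` has the code column (named after ``code_kind``) and any
    annotation columns (e.g. condition, subgroup) to be carried through to
    query output.
    """

    code_kind: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.code_kind not in CODE_KINDS:
            raise ValueError(f"code_kind must be one of {CODE_KINDS}")
        if self.code_kind not in self.table.columns:
            raise ValueError(f"codelist table lacks a {self.code_kind!r} column")
        codes = self.table[self.code_kind]
        if codes.isna().any() or (codes.astype(str).str.strip() == "").any():
            raise ValueError("codelist contains empty codes")

    @property
    def codes(self) -> list[str]:
        return self.table[self.code_kind].astype(str).unique().tolist()

    @property
    def annotations(self) -> list[str]:
        return [c for c in self.table.columns if c != self.code_kind]

    def __len__(self) -> int:
        return len(self.codes)

    @classmethod
    def from_vector(cls, codes: Iterable[str], code_kind: str = "medcodeid") -> "Codelist":
        return cls(code_kind, pd.DataFrame({code_kind: [str(c) for c in codes]}))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Codelist":
        kinds = [k for k in CODE_KINDS if k in frame.columns]
        if len(kinds) != 1:
            raise ValueError(
                f"codelist frame must contain exactly one of {CODE_KINDS}; "
                f"found {kinds or list(frame.columns)}"
            )
        frame = frame.copy()
        frame[kinds[0]] = frame[kinds[0]].astype(str)
        return cls(kinds[0], frame)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Codelist":
        frame = pd.read_csv(path, dtype=str)
        return cls.from_frame(frame)

    @classmethod
    def coerce(cls, obj, code_kind: str = "medcodeid") -> "Codelist":
        if isinstance(obj, Codelist):
            return obj
        if isinstance(obj, pd.DataFrame):
            return cls.from_frame(obj)
        if isinstance(obj, (str, Path)) and str(obj).endswith(".csv"):
            return cls.from_csv(obj)
        if isinstance(obj, (list, tuple, set, frozenset, pd.Series, np.ndarray)):
            return cls.from_vector(obj, code_kind)
        raise TypeError(f"cannot interpret {type(obj).__name__} as a codelist")


# ---------------------------------------------------------------------------
# Store queries
# ---------------------------------------------------------------------------

def db_query(
    codelist: Codelist | pd.DataFrame | Sequence[str],
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    rm_duplicates: bool = False,
    layout=None,
) -> pd.DataFrame:
    """All rows of table *tab* whose code is in *codelist*.

    The code column queried is the codelist's kind (``medcodeid``,
    ``prodcodeid`` or ``ICD10``); a codelist whose kind is not a column of
    the table is an error.  Date columns come back parsed.  When the
    codelist carries annotation columns they are joined onto the result by
    code.  The store may be an open handle, or be named per the workspace
    convention (``db_name`` → ``data/sql/<name>.sqlite``) in which case the
    connection is opened and closed internally.
    """
    codelist = Codelist.coerce(codelist)
    if store is not None:
        return _db_query_open(codelist, store, tab, rm_duplicates)
    from .workspace import resolve_store

    with resolve_store(db_name=db_name, db_filepath=db_filepath, layout=layout) as handle:
        return _db_query_open(codelist, handle, tab, rm_duplicates)


def _db_query_open(
    codelist: Codelist, store: StoreHandle, tab: str, rm_duplicates: bool
) -> pd.DataFrame:
    cols = _table_columns(store, tab)
    if cols is None:
        raise ValueError(f"no table named {tab!r} in store {store.db_path}")
    kind = codelist.code_kind
    if kind not in cols:
        raise ValueError(
            f"codelist kind {kind!r} incompatible with table {tab!r} "
            f"(columns: {cols})"
        )
    frames = []
    codes = codelist.codes
    for i in range(0, len(codes), 500):
        batch = codes[i : i + 500]
        placeholders = ",".join("?" * len(batch))
        frames.append(
            pd.read_sql_query(
                f'SELECT * FROM "{tab}" WHERE "{kind}" IN ({placeholders})',
                store.conn,
                params=batch,
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
    if out.empty and list(out.columns) != cols:
        out = pd.DataFrame(columns=cols)
    if rm_duplicates:
        out = out.drop_duplicates(ignore_index=True)
    for col in ("obsdate", "issuedate", "admidate", "dod", "dor"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col], format="%Y-%m-%d", errors="coerce")
    if codelist.annotations:
        ann = codelist.table.copy()
        ann[kind] = ann[kind].astype(str)
        out = out.merge(ann, on=kind, how="left")
    return out


# ---------------------------------------------------------------------------
# Cohort combinators
# ---------------------------------------------------------------------------

def _event_date_column(query: pd.DataFrame) -> str:
    for col in ("obsdate", "issuedate", "admidate"):
        if col in query.columns:
            return col
    raise ValueError(
        "query has no recognized event-date column (obsdate/issuedate/admidate)"
    )


def _windowed_merge(
    cohort: pd.DataFrame,
    query: pd.DataFrame,
    time_prev: float,
    time_post: float,
    t_offset: int,
) -> tuple[pd.DataFrame, str]:
    """Merge query rows with cohort index dates and apply the event window."""
    validate_cohort(cohort)
    if time_prev < 0 or time_post < 0:
        raise ValueError("time_prev and time_post must be non-negative")
    date_col = _event_date_column(query)
    idx = cohort[["patid", "indexdt"]].copy()
    idx["patid"] = idx["patid"].astype(str)
    idx["indexdt"] = pd.to_datetime(idx["indexdt"])
    merged = query.merge(idx, on="patid", how="inner")
    ref = merged["indexdt"] + pd.to_timedelta(t_offset, unit="D")
    dates = pd.to_datetime(merged[date_col])
    keep = dates.notna()
    if math.isfinite(time_prev):
        keep &= dates >= ref - pd.to_timedelta(int(time_prev), unit="D")
    if math.isfinite(time_post):
        keep &= dates <= ref + pd.to_timedelta(int(time_post), unit="D")
    return merged[keep].copy(), date_col


def combine_query(
    cohort: pd.DataFrame,
    query: pd.DataFrame,
    query_type: str = "med",
    time_prev: float = math.inf,
    time_post: float = 0,
    lower_bound: float = -math.inf,
    upper_bound: float = math.inf,
    numobs: int = 1,
    value_na_rm: bool = True,
    reduce_output: bool = True,
    t_offset: int = 0,
) -> pd.DataFrame:
    """Per patient, the most recent *numobs* in-window (and in-bounds) rows.

    ``query_type`` selects the semantics: ``'med'`` keeps event date and
    medcodeid; ``'test'`` additionally applies value bounds and missing-value
    removal and keeps value/unit metadata; ``'drug'`` keeps event date and
    prodcodeid.  Rows are sorted most-recent-first within patient (ties:
    higher value first for tests, otherwise stable input order) and the
    first *numobs* kept; patients with fewer matching rows return what
    exists.
    """
    if query_type not in ("med", "test", "drug"):
        raise ValueError("query_type must be 'med', 'test' or 'drug'")
    if numobs < 1:
        raise ValueError("numobs must be a positive integer")
    merged, date_col = _windowed_merge(cohort, query, time_prev, time_post, t_offset)

    if query_type == "test":
        if "value" not in merged.columns:
            raise ValueError("test query requires a 'value' column")
        merged["value"] = pd.to_numeric(merged["value"], errors="coerce")
        if value_na_rm:
            merged = merged[merged["value"].notna()]
        in_bounds = (merged["value"] >= lower_bound) & (merged["value"] <= upper_bound)
        merged = merged[merged["value"].isna() | in_bounds]

    # Most recent first; ties broken by higher value for tests, else by
    # stable input order.
    merged = merged.reset_index(drop=True)
    if query_type == "test":
        order = merged.sort_values(
            [date_col, "value"], ascending=[False, False], kind="stable"
        )
    else:
        order = merged.sort_values(date_col, ascending=False, kind="stable")
    out = order.groupby("patid", sort=True).head(numobs).reset_index(drop=True)

    if reduce_output:
        keep = {
            "med": ["patid", date_col, "medcodeid"],
            "drug": ["patid", date_col, "prodcodeid"],
            "test": ["patid", date_col, "medcodeid", "value", "numunitid"],
        }[query_type]
        out = out[[c for c in keep if c in out.columns]]
    return out


def combine_query_boolean(
    cohort: pd.DataFrame,
    query: pd.DataFrame,
    time_prev: float = math.inf,
    time_post: float = 0,
    t_offset: int = 0,
) -> np.ndarray:
    """0/1 per cohort row: does the patient have any in-window query record?

    Output order matches the cohort's row order; a cohort patient absent
    from the query is 0.
    """
    merged, _ = _windowed_merge(cohort, query, time_prev, time_post, t_offset)
    hit = set(merged["patid"].astype(str))
    return cohort["patid"].astype(str).isin(hit).to_numpy().astype(int)


# ---------------------------------------------------------------------------
# Brute-force raw-file oracle
# ---------------------------------------------------------------------------

def brute_force_history(
    raw_dir: str | Path,
    cohort: pd.DataFrame,
    codelist: Codelist | pd.DataFrame | Sequence[str],
    t_offset: int = 0,
    settings: Settings = DEFAULT_SETTINGS,
) -> np.ndarray:
    """History-of flags computed by looping over the raw observation files.

    This is the manual approach the store exists to avoid, retained as an
    independent check: create a zero vector over the cohort, then for each
    raw observation file in turn — read it, format the observation date,
    subset to the codelist, merge with the cohort, drop records after the
    (offset) index date, and flag the patients that remain.  The store is
    never touched.
    """
    validate_cohort(cohort)
    codelist = Codelist.coerce(codelist)
    code_set = set(codelist.codes)
    paths = scan_directory(raw_dir, "observation")
    if not paths:
        raise FileNotFoundError(f"no observation files in {raw_dir}")

    # Step 1: zero disease-status vector over the cohort.
    flags = np.zeros(len(cohort), dtype=int)
    pos_of_patid = {str(p): i for i, p in enumerate(cohort["patid"])}
    indexdt = pd.Series(
        pd.to_datetime(cohort["indexdt"]).to_numpy()
        + np.timedelta64(t_offset, "D"),
        index=cohort["patid"].astype(str),
    )

    for path in paths:
        # Step 2: read the raw file and format obsdate as a date.
        tab = pd.read_csv(
            path, sep=settings.delimiter, dtype=str, keep_default_na=False,
            na_values=[""],
        )
        obsdate = pd.Series(pd.NaT, index=tab.index, dtype="datetime64[ns]")
        remaining = tab["obsdate"].notna()
        for fmt in settings.date_formats:
            if not remaining.any():
                break
            parsed = pd.to_datetime(tab.loc[remaining, "obsdate"], format=fmt, errors="coerce")
            obsdate.loc[remaining] = parsed
            remaining &= parsed.isna().reindex(tab.index, fill_value=False)
        # Step 3: subset to codelist codes.
        hit = tab["medcodeid"].isin(code_set)
        # Step 4: merge with cohort; drop records not prior to the index date.
        sub = tab.loc[hit, ["patid"]].copy()
        sub["obsdate"] = obsdate[hit]
        sub = sub[sub["patid"].isin(indexdt.index)]
        limit = indexdt.loc[sub["patid"]].to_numpy()
        if settings.history_inclusive:
            prior = sub["obsdate"].to_numpy() <= limit
        else:
            prior = sub["obsdate"].to_numpy() < limit
        # Step 5: flag those patients.
        for patid in sub.loc[prior, "patid"]:
            flags[pos_of_patid[patid]] = 1
    return flags
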