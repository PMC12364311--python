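"""Cohort construction.

A cohort is, at heart, a vector of patient identifiers: the patients meeting
a study's inclusion/exclusion criteria, carried in a table together with the
per-patient index date (``indexdt``) that every downstream variable is
computed relative to, and optionally a censoring date (``censdt``).
Inclusion/exclusion predicates themselves are ordinary table filtering and
are left to the caller; this module concatenates the raw patient files,
subsets to known IDs, and assigns index dates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .config import DEFAULT_SETTINGS, Settings, logger
from .raw_io import parse_filename, read_raw_file, scan_directory

__all__ = ["extract_cohort", "assign_index_dates", "validate_cohort"]


def _natural_patid_key(s: pd.Series) -> pd.Series:
    """Numeric-aware sort key for text patient IDs ('2' before '10')."""
    num = pd.to_numeric(s, errors="coerce")
    return pd.Series(list(zip(num.isna(), num.fillna(0), s.astype(str))), index=s.index)


def extract_cohort(
    filepath: str | Path,
    patids: Iterable[str] | None = None,
    set_flag: bool = False,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Read and concatenate every patient file under *filepath*.

    Any ``.txt`` file whose name contains ``patient`` (case-insensitive) is
    read.  If *patids* is given, only rows with those patient IDs are kept.
    With ``set_flag=True`` a ``set`` column is added, parsed from each source
    filename — the input needed for the set-aware ingest fast path.

    The result is sorted by patient ID (numeric-aware) so it does not depend
    on directory listing order.  A patient ID occurring in more than one
    patient file is an error.
    """
    filepath = Path(filepath)
    if not filepath.is_dir():
        raise FileNotFoundError(f"not a directory: {filepath}")
    paths = scan_directory(filepath, "patient")
    if not paths:
        raise FileNotFoundError(f"no patient files found in {filepath}")

    frames = []
    for path in paths:
        tab = read_raw_file(path, filetype="patient", settings=settings)
        if set_flag:
            tab = tab.copy()
            tab["set"] = parse_filename(path.name).set_number
        frames.append(tab)
        logger.info("read %d patient rows from %s", len(tab), path.name)
    out = pd.concat(frames, ignore_index=True)

    dup = out["patid"][out["patid"].duplicated()].unique()
    if len(dup):
        raise ValueError(
            f"duplicate patid across patient files: {sorted(dup.tolist())}"
        )
    if patids is not None:
        wanted = {str(p) for p in patids}
        out = out[out["patid"].isin(wanted)]
    out = out.iloc[_natural_patid_key(out["patid"]).argsort(kind="stable")]
    return out.reset_index(drop=True)


def assign_index_dates(
    patients: pd.DataFrame,
    fixed_date: object | None = None,
    column: str | None = None,
) -> pd.DataFrame:
    """Return a cohort with an ``indexdt`` column populated for every row.

    The index date rule is a fixed calendar date, a per-patient date column,
    or — when both are given — the elementwise maximum of the two (e.g. the
    later of 1 Jan 2010 and the date a patient turned 50).  A missing date
    under a per-patient rule is an error listing the offending patients.
    """
    if fixed_date is None and column is None:
        raise ValueError("give fixed_date, column, or both")
    out = patients.copy()
    if column is not None:
        if column not in out.columns:
            raise KeyError(f"index-date column {column!r} not in cohort")
        per_patient = pd.to_datetime(out[column])
        missing = out.loc[per_patient.isna(), "patid"]
        if len(missing):
            raise ValueError(
                f"missing index date in column {column!r} for patids: "
                f"{missing.tolist()}"
            )
        if fixed_date is not None:
            out["indexdt"] = per_patient.clip(lower=pd.Timestamp(fixed_date))
        else:
            out["indexdt"] = per_patient
    else:
        out["indexdt"] = pd.Timestamp(fixed_date)
    return out


def validate_cohort(cohort: pd.DataFrame, require_censdt: bool = False) -> None:
    """Check the cohort invariants used by the extraction functions."""
    if "patid" not in cohort.columns:
        raise ValueError("cohort lacks a 'patid' column")
    if "indexdt" not in cohort.columns:
        raise ValueError("cohort lacks an 'indexdt' column; assign index dates first")
    if cohort["patid"].duplicated().any():
        raise ValueError("cohort patid values are not unique")
    if require_censdt:
        if "censdt" not in cohort.columns:
            raise ValueError("this extraction requires a 'censdt' censoring column")
        cens = pd.to_datetime(cohort["censdt"])
        idx = pd.to_datetime(cohort["indexdt"])
        bad = cohort.loc[cens.isna() | (cens < idx), "patid"]
        if len(bad):
            raise ValueError(
                f"censdt missing or earlier than indexdt for patids: {bad.tolist()}"
            )
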