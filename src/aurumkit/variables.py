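"""Named per-patient analysis variables.

Every function here turns a codelist-driven query of the store into one
column (or column pair) of the analysis-ready dataset, computed relative to
each patient's index date:

* :func:`extract_ho` — binary "history of" flag (any matching record on or
  before the index date);
* :func:`extract_time_until` — time-to-event pair (days until first
  matching record after the index date, or censoring);
* :func:`extract_test_data` / :func:`extract_test_data_var` — most recent
  valid test value(s) in a window, and their standard deviation;
* :func:`extract_bmi`, :func:`extract_cholhdl_ratio`,
  :func:`extract_diabetes`, :func:`extract_smoking` — phenotypes whose
  definitions need bespoke cleaning rules.

All functions accept a ``t_offset`` (days added to the index date) so the
same variable can be re-extracted at fixed intervals for longitudinal
analyses; nonzero offsets are embedded in saved filenames.  Codelists and
stores may be passed directly or referred to by workspace name.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import validate_cohort
from .config import DEFAULT_SETTINGS, Settings, logger
from .database import StoreHandle
from .query import Codelist, combine_query, combine_query_boolean, db_query
from . import workspace as ws

__all__ = [
    "extract_ho",
    "extract_time_until",
    "extract_test_data",
    "extract_test_data_var",
    "extract_bmi",
    "extract_cholhdl_ratio",
    "extract_diabetes",
    "extract_smoking",
    "SMOKING_CATEGORIES",
]

#: Default search window for the bespoke phenotype variables: five years
#: before the index date, nothing after.  Configurable per call.
DEFAULT_TIME_PREV = 1825
DEFAULT_TIME_POST = 0


def _codelist(
    codelist,
    codelist_vector,
    layout,
    code_kind: str = "medcodeid",
) -> Codelist:
    """Resolve a codelist argument; an explicit vector takes precedence, a
    bare string is a workspace codelist name."""
    if codelist_vector is not None:
        return Codelist.from_vector(codelist_vector, code_kind)
    if codelist is None:
        raise ValueError("no codelist given")
    if isinstance(codelist, str) and not codelist.endswith(".csv"):
        return ws.resolve_codelist(codelist_name=codelist, layout=layout)
    return Codelist.coerce(codelist, code_kind)


def _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout):
    if out_save_disk or out_filepath is not None:
        path = ws.save_variable(out, varname, t_offset, out_filepath, layout)
        logger.info("saved variable %r to %s", varname, path)
    return out


def _kind_for_table(tab: str) -> str:
    if "drugissue" in tab:
        return "prodcodeid"
    if "hes" in tab:
        return "ICD10"
    return "medcodeid"


def extract_ho(
    cohort: pd.DataFrame,
    codelist=None,
    codelist_vector: Iterable[str] | None = None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    t_offset: int = 0,
    varname: str = "ho",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Binary history-of flag: any matching record on or before the index
    date (plus *t_offset* days).

    Works for medical diagnoses (``tab='observation'``) or prescriptions
    (``tab='drugissue'``).  Returns one row per cohort patient with columns
    ``patid`` and *varname*.
    """
    validate_cohort(cohort)
    cl = _codelist(codelist, codelist_vector, layout, _kind_for_table(tab))
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        q = db_query(cl, store=h, tab=tab)
    t_adj = t_offset if settings.history_inclusive else t_offset - 1
    flags = combine_query_boolean(cohort, q, time_prev=math.inf, time_post=0, t_offset=t_adj)
    out = pd.DataFrame({"patid": cohort["patid"].astype(str), varname: flags})
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


def extract_time_until(
    cohort: pd.DataFrame,
    codelist=None,
    codelist_vector: Iterable[str] | None = None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    t_offset: int = 0,
    varname: str = "event",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Time-to-event pair ``(<varname>_time, <varname>_indicator)``.

    Let e be the earliest matching record strictly after the (offset) index
    date.  If e exists and is on or before the censoring date the patient
    contributes ``(e − index, 1)``; otherwise ``(censdt − index, 0)``.  The
    cohort must carry a ``censdt`` column with ``censdt ≥ indexdt``.
    """
    validate_cohort(cohort, require_censdt=True)
    cl = _codelist(codelist, codelist_vector, layout, _kind_for_table(tab))
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        q = db_query(cl, store=h, tab=tab)

    date_col = "issuedate" if "issuedate" in q.columns else "obsdate"
    base = cohort[["patid", "indexdt", "censdt"]].copy()
    base["patid"] = base["patid"].astype(str)
    base["ref"] = pd.to_datetime(base["indexdt"]) + pd.to_timedelta(t_offset, unit="D")
    base["censdt"] = pd.to_datetime(base["censdt"])

    ev = q[["patid", date_col]].dropna().copy()
    ev["patid"] = ev["patid"].astype(str)
    ev = ev.merge(base[["patid", "ref"]], on="patid", how="inner")
    after = ev[date_col] > ev["ref"] if settings.time_until_strict else ev[date_col] >= ev["ref"]
    first = (
        ev[after]
        .groupby("patid", sort=False)[date_col]
        .min()
        .rename("first_event")
    )
    base = base.merge(first, left_on="patid", right_index=True, how="left")

    observed = base["first_event"].notna() & (base["first_event"] <= base["censdt"])
    end = base["censdt"].where(~observed, base["first_event"])
    out = pd.DataFrame(
        {
            "patid": base["patid"],
            f"{varname}_time": (end - base["ref"]).dt.days,
            f"{varname}_indicator": observed.astype(int),
        }
    )
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


def extract_test_data(
    cohort: pd.DataFrame,
    codelist=None,
    codelist_vector: Iterable[str] | None = None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    time_prev: float = DEFAULT_TIME_PREV,
    time_post: float = DEFAULT_TIME_POST,
    lower_bound: float = -math.inf,
    upper_bound: float = math.inf,
    numobs: int = 1,
    with_metadata: bool = False,
    value_na_rm: bool = True,
    t_offset: int = 0,
    varname: str = "test",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Most recent valid test value(s) in a window around the index date.

    Values outside ``[lower_bound, upper_bound]`` are dropped, missing
    values are dropped when *value_na_rm*, and up to *numobs* rows per
    patient are returned, most recent first.  ``with_metadata=True`` keeps
    the observation date, medical code and unit code alongside the value.
    Patients with no valid in-window value contribute no rows.
    """
    validate_cohort(cohort)
    cl = _codelist(codelist, codelist_vector, layout, "medcodeid")
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        q = db_query(cl, store=h, tab=tab)
    res = combine_query(
        cohort,
        q,
        query_type="test",
        time_prev=time_prev,
        time_post=time_post,
        lower_bound=lower_bound,
        upper_bound=upper_bound,
        numobs=numobs,
        value_na_rm=value_na_rm,
        reduce_output=True,
        t_offset=t_offset,
    )
    out = res.rename(columns={"value": varname})
    if not with_metadata:
        out = out[["patid", varname]]
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


def extract_test_data_var(
    cohort: pd.DataFrame,
    codelist=None,
    codelist_vector: Iterable[str] | None = None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    time_prev: float = DEFAULT_TIME_PREV,
    time_post: float = DEFAULT_TIME_POST,
    lower_bound: float = -math.inf,
    upper_bound: float = math.inf,
    t_offset: int = 0,
    varname: str = "test_sd",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Sample standard deviation (divisor n−1) of all valid in-window
    test values; missing when a patient has fewer than two values.
    One row per cohort patient."""
    validate_cohort(cohort)
    cl = _codelist(codelist, codelist_vector, layout, "medcodeid")
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        q = db_query(cl, store=h, tab=tab)
    res = combine_query(
        cohort,
        q,
        query_type="test",
        time_prev=time_prev,
        time_post=time_post,
        lower_bound=lower_bound,
        upper_bound=upper_bound,
        numobs=max(len(q), 1),
        value_na_rm=True,
        reduce_output=True,
        t_offset=t_offset,
    )
    sd = res.groupby("patid")[varname if varname in res else "value"].std(ddof=1)
    out = pd.DataFrame({"patid": cohort["patid"].astype(str)})
    out[varname] = out["patid"].map(sd)
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


# ---------------------------------------------------------------------------
# Bespoke phenotypes
# ---------------------------------------------------------------------------

def _most_recent_test(cohort, cl, handle, tab, time_prev, time_post, t_offset):
    """patid-indexed frame of the single most recent valid value + metadata."""
    q = db_query(cl, store=handle, tab=tab)
    res = combine_query(
        cohort,
        q,
        query_type="test",
        time_prev=time_prev,
        time_post=time_post,
        numobs=1,
        t_offset=t_offset,
    )
    return res.set_index("patid")


def _height_metres(values: pd.Series, units: pd.Series, settings: Settings) -> pd.Series:
    """Convert raw height records to metres.

    Records whose unit code maps in ``settings.height_unit_scale`` are
    scaled accordingly; unmapped records above the centimetre heuristic
    threshold are assumed to be centimetres.
    """
    units = units.astype(str).str.strip().str.lower()
    factor = units.map(lambda u: settings.height_unit_scale.get(u, np.nan))
    heuristic = np.where(values > settings.height_cm_heuristic, 0.01, 1.0)
    return values * factor.fillna(pd.Series(heuristic, index=values.index))


def _composite_phenotype(
    cohort,
    direct: pd.DataFrame,
    comp_a: pd.DataFrame,
    comp_b: pd.DataFrame,
    combine,
    varname: str,
) -> pd.DataFrame:
    """Choose, per patient, between a directly recorded value and one
    computed from two components, by recency of the governing date (the
    later component date for the computed candidate; ties favour direct)."""
    out = pd.DataFrame({"patid": cohort["patid"].astype(str)})
    d_val = out["patid"].map(direct["value"]) if len(direct) else pd.Series(np.nan, index=out.index)
    d_date = out["patid"].map(direct["obsdate"]) if len(direct) else pd.Series(pd.NaT, index=out.index)
    a_val = out["patid"].map(comp_a["value"]) if len(comp_a) else pd.Series(np.nan, index=out.index)
    a_date = out["patid"].map(comp_a["obsdate"]) if len(comp_a) else pd.Series(pd.NaT, index=out.index)
    b_val = out["patid"].map(comp_b["value"]) if len(comp_b) else pd.Series(np.nan, index=out.index)
    b_date = out["patid"].map(comp_b["obsdate"]) if len(comp_b) else pd.Series(pd.NaT, index=out.index)

    computed = combine(a_val, b_val)
    computed_date = pd.concat([a_date, b_date], axis=1).max(axis=1)
    computed_date = computed_date.where(computed.notna(), pd.NaT)

    use_direct = d_val.notna() & (computed.isna() | (d_date >= computed_date))
    value = np.where(use_direct, d_val, computed)
    out[varname] = value
    return out


def extract_bmi(
    cohort: pd.DataFrame,
    codelist_bmi=None,
    codelist_height=None,
    codelist_weight=None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    time_prev: float = DEFAULT_TIME_PREV,
    time_post: float = DEFAULT_TIME_POST,
    t_offset: int = 0,
    varname: str = "bmi",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Body-mass index, directly recorded or derived as weight/height².

    Separate codelists identify direct BMI records, height records and
    weight records.  The computed candidate uses the most recent in-window
    weight and the most recent in-window height (heights recorded in
    centimetres are converted to metres via the unit code); its governing
    date is the later of the two component dates.  Whichever candidate has
    the more recent governing date wins; ties favour the direct record.
    Non-positive heights after conversion are skipped with a logged count.
    """
    validate_cohort(cohort)
    cls = [
        _codelist(c, None, layout) for c in (codelist_bmi, codelist_height, codelist_weight)
    ]
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        direct, height, weight = (
            _most_recent_test(cohort, c, h, tab, time_prev, time_post, t_offset)
            for c in cls
        )

    if len(height):
        height = height.copy()
        height["value"] = _height_metres(height["value"], height["numunitid"], settings)
        bad = height["value"].notna() & (height["value"] <= 0)
        if bad.any():
            logger.warning("%d non-positive height(s) after unit conversion skipped", int(bad.sum()))
            height = height[~bad]

    out = _composite_phenotype(
        cohort, direct, weight, height,
        combine=lambda w, hgt: w / hgt**2,
        varname=varname,
    )
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


def extract_cholhdl_ratio(
    cohort: pd.DataFrame,
    codelist_ratio=None,
    codelist_chol=None,
    codelist_hdl=None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    time_prev: float = DEFAULT_TIME_PREV,
    time_post: float = DEFAULT_TIME_POST,
    t_offset: int = 0,
    varname: str = "cholhdl_ratio",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Total-cholesterol/HDL ratio, direct or total/HDL from components.

    Candidate logic mirrors :func:`extract_bmi`; a component candidate with
    HDL equal to zero is invalid.
    """
    validate_cohort(cohort)
    cls = [
        _codelist(c, None, layout) for c in (codelist_ratio, codelist_chol, codelist_hdl)
    ]
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        direct, chol, hdl = (
            _most_recent_test(cohort, c, h, tab, time_prev, time_post, t_offset)
            for c in cls
        )
    if len(hdl):
        hdl = hdl[hdl["value"] != 0]

    out = _composite_phenotype(
        cohort, direct, chol, hdl,
        combine=lambda c, hd: c / hd,
        varname=varname,
    )
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


def extract_diabetes(
    cohort: pd.DataFrame,
    codelist_type1=None,
    codelist_type2=None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    t_offset: int = 0,
    varname: str = "diabetes",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Diabetes status: ``Absent``, ``type1`` or ``type2``.

    Any pre-index type-1 code makes the patient type 1, even when type-2
    codes are also present; otherwise any pre-index type-2 code makes them
    type 2.  Generic diabetes codes that do not state a type belong in the
    type-2 codelist: they are read as type 2 unless a specific type-1 code
    exists for the same patient — which the precedence rule already
    handles.
    """
    validate_cohort(cohort)
    ho1 = extract_ho(
        cohort, codelist_type1, store=store, db_name=db_name,
        db_filepath=db_filepath, tab=tab, t_offset=t_offset, varname="t1",
        layout=layout, settings=settings,
    )["t1"].to_numpy()
    ho2 = extract_ho(
        cohort, codelist_type2, store=store, db_name=db_name,
        db_filepath=db_filepath, tab=tab, t_offset=t_offset, varname="t2",
        layout=layout, settings=settings,
    )["t2"].to_numpy()
    status = np.where(ho1 == 1, "type1", np.where(ho2 == 1, "type2", "Absent"))
    out = pd.DataFrame({"patid": cohort["patid"].astype(str), varname: status})
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)


SMOKING_CATEGORIES = ("Non-smoker", "Ex-smoker", "Light smoker", "Moderate smoker", "Heavy smoker")

#: Tie-break priority for same-day records: heavier status wins, so a
#: same-day non-smoker record never masks a smoking record.
_SMOKING_PRIORITY = {c: i for i, c in enumerate(SMOKING_CATEGORIES)}


def extract_smoking(
    cohort: pd.DataFrame,
    codelist_non=None,
    codelist_ex=None,
    codelist_light=None,
    codelist_moderate=None,
    codelist_heavy=None,
    store: StoreHandle | None = None,
    db_name: str | None = None,
    db_filepath: str | Path | None = None,
    tab: str = "observation",
    t_offset: int = 0,
    varname: str = "smoking",
    out_save_disk: bool = False,
    out_filepath: str | Path | None = None,
    layout=None,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Smoking status from five per-category codelists.

    The status is the category of the most recent pre-index smoking record.
    If that record says non-smoker but earlier records indicate any
    smoking (ex/light/moderate/heavy), the patient is reclassified as an
    ex-smoker.  Patients with no smoking records are missing.  A code
    appearing in two codelists is an error (ambiguous categories).
    """
    validate_cohort(cohort)
    lists = {
        "Non-smoker": codelist_non,
        "Ex-smoker": codelist_ex,
        "Light smoker": codelist_light,
        "Moderate smoker": codelist_moderate,
        "Heavy smoker": codelist_heavy,
    }
    resolved = {cat: _codelist(cl, None, layout) for cat, cl in lists.items()}
    seen: dict[str, str] = {}
    for cat, cl in resolved.items():
        for code in cl.codes:
            if code in seen:
                raise ValueError(
                    f"code {code!r} appears in both {seen[code]!r} and {cat!r} codelists"
                )
            seen[code] = cat

    frames = []
    with ws.resolve_store(store, db_name, db_filepath, layout) as h:
        for cat, cl in resolved.items():
            q = db_query(cl, store=h, tab=tab)
            if len(q):
                q = q[["patid", "obsdate"]].copy()
                q["category"] = cat
                frames.append(q)

    out = pd.DataFrame({"patid": cohort["patid"].astype(str)})
    if not frames:
        out[varname] = pd.Series(pd.NA, index=out.index, dtype="string")
        return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)

    records = pd.concat(frames, ignore_index=True)
    records["patid"] = records["patid"].astype(str)
    t_adj = t_offset if settings.history_inclusive else t_offset - 1
    idx = cohort[["patid"]].copy()
    idx["patid"] = idx["patid"].astype(str)
    idx["ref"] = pd.to_datetime(cohort["indexdt"]).to_numpy() + np.timedelta64(t_adj, "D")
    records = records.merge(idx, on="patid", how="inner")
    records = records[records["obsdate"].notna() & (records["obsdate"] <= records["ref"])]

    records["priority"] = records["category"].map(_SMOKING_PRIORITY)
    records = records.sort_values(
        ["obsdate", "priority"], ascending=[False, False], kind="stable"
    )
    latest = records.groupby("patid", sort=False).first()
    ever_smoked = (
        records[records["category"] != "Non-smoker"].groupby("patid", sort=False).size()
    )

    status = latest["category"].copy()
    reclass = (status == "Non-smoker") & status.index.isin(ever_smoked.index)
    status[reclass] = "Ex-smoker"
    out[varname] = out["patid"].map(status).astype("string")
    return _maybe_save(out, varname, t_offset, out_save_disk, out_filepath, layout)
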