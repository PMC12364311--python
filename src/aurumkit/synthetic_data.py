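"""Synthetic raw-extract generation.

Real primary-care extracts cannot be redistributed, so every other module is
exercised against generated file trees with the same shape: tab-delimited
``.txt`` files under the ``<prefix>_setX_extract_<filetype>_0Y.txt`` naming
convention.  Two generators are provided:

* :func:`generate_fixture` — a small worked-example tree (by default 12
  patients split across two patient files, with three observation and three
  drug-issue files all in set 1).  Simulation recipe: numeric values are
  uniform integers 1–100, dates uniform between 1900-01-01 and 2000-01-01,
  gender 1 or 2, year of birth uniform 1900–2000; patient and practice IDs
  are assigned sequentially.
* :func:`generate_study` — larger randomized trees in which selected codes
  are planted pre-index with known per-patient probabilities, and the
  ground-truth flags are written to a sidecar CSV.  This gives every
  extraction path an exact oracle: the truth file says which patients must
  come out flagged.

Fixed seed implies byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SETTINGS, Settings
from .raw_io import format_filename, write_raw_file

__all__ = [
    "FileEntry",
    "FixtureManifest",
    "StudyRecipe",
    "generate_fixture",
    "generate_study",
    "DEFAULT_PREFIX",
    "FIXTURE_MEDCODES",
]

DEFAULT_PREFIX = "aurum_allpatid"

#: Medical codes used in the worked-example fixture.  Aurum-sized numeric
#: strings; the first one is the code queried in the worked example.
FIXTURE_MEDCODES = (
    "187341000000114",
    "498521000006119",
    "401539014",
    "216201011",
    "2897161000006114",
)

FIXTURE_PRODCODES = (
    "1026541000033111",
    "320139002",
    "3424521000033110",
    "244196011",
)

_SIM_DATE_START = "1900-01-01"
_SIM_DATE_END = "2000-01-01"


@dataclass(frozen=True)
class FileEntry:
    filename: str
    filetype: str
    set_number: int
    part_number: int
    n_rows: int


@dataclass(frozen=True)
class FixtureManifest:
    """Every file written by a generator call, and nothing else."""

    root_dir: str
    files: tuple[FileEntry, ...]
    seed: int

    def filenames(self, filetype: str | None = None) -> list[str]:
        return [
            f.filename for f in self.files if filetype is None or f.filetype == filetype
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "root_dir": self.root_dir,
            "seed": self.seed,
            "files": [dataclasses.asdict(f) for f in self.files],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            root_dir=payload["root_dir"],
            files=tuple(FileEntry(**f) for f in payload["files"]),
            seed=payload["seed"],
        )


@dataclass(frozen=True)
class StudyRecipe:
    """Parameters of a randomized study-scale file tree.

    ``code_prevalences`` maps a medical code to the probability that each
    patient independently receives at least one observation with that code
    dated strictly before ``index_date``.  All other observations draw codes
    from a disjoint background pool, so the planted flags are exactly the
    set of patients with any record of the code.
    """

    n_patients: int
    n_sets: int = 2
    obs_files_per_set: int = 2
    drug_files_per_set: int = 1
    obs_per_patient: float = 50.0
    drugs_per_patient: float = 10.0
    code_prevalences: Mapping[str, float] = field(default_factory=dict)
    index_date: date = date(2010, 1, 1)
    seed: int = 0
    prefix: str = DEFAULT_PREFIX

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for n, label in [
            (self.n_sets, "n_sets"),
            (self.obs_files_per_set, "obs_files_per_set"),
            (self.drug_files_per_set, "drug_files_per_set"),
        ]:
            if n <= 0:
                raise ValueError(f"{label} must be positive")
        for code, p in self.code_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {code!r} outside [0, 1]: {p}")


# ---------------------------------------------------------------------------
# Random primitives
# ---------------------------------------------------------------------------

def _rand_dates(
    rng: np.random.Generator, n: int, start: str, end: str
) -> pd.Series:
    """Uniform dates in [start, end], at day resolution."""
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    span = (end_ts - start_ts).days
    offsets = rng.integers(0, span + 1, size=n)
    return pd.Series(start_ts + pd.to_timedelta(offsets, unit="D"))


def _rand_ints(rng: np.random.Generator, n: int, lo: int = 1, hi: int = 100):
    return rng.integers(lo, hi + 1, size=n)


def _patient_table(rng: np.random.Generator, patids: Sequence[str]) -> pd.DataFrame:
    n = len(patids)
    reg = _rand_dates(rng, n, _SIM_DATE_START, _SIM_DATE_END)
    return pd.DataFrame(
        {
            "patid": list(patids),
            "pracid": [str(i + 1) for i in range(n)],
            "usualgpstaffid": _rand_ints(rng, n).astype(str),  # inert filler
            "gender": _rand_ints(rng, n, 1, 2),
            "yob": _rand_ints(rng, n, 1900, 2000),
            "regstartdate": reg,
            "patienttypeid": _rand_ints(rng, n).astype(str),  # inert filler
            "regenddate": _rand_dates(rng, n, _SIM_DATE_START, _SIM_DATE_END),
            "cprd_ddate": _rand_dates(rng, n, _SIM_DATE_START, _SIM_DATE_END),
        }
    )


def _observation_table(
    rng: np.random.Generator,
    patids: np.ndarray,
    codes: np.ndarray,
    dates: pd.Series,
) -> pd.DataFrame:
    n = len(patids)
    return pd.DataFrame(
        {
            "patid": patids,
            "consid": _rand_ints(rng, n).astype(str),  # inert filler
            "medcodeid": codes,
            "obsdate": dates.to_numpy(),
            "enterdate": _rand_ints(rng, n).astype(str),  # inert filler
            "value": _rand_ints(rng, n),
            "numunitid": _rand_ints(rng, n).astype(str),
        }
    )


def _drugissue_table(
    rng: np.random.Generator,
    patids: np.ndarray,
    codes: np.ndarray,
    dates: pd.Series,
) -> pd.DataFrame:
    n = len(patids)
    return pd.DataFrame(
        {
            "patid": patids,
            "prodcodeid": codes,
            "issuedate": dates.to_numpy(),
            "dosageid": _rand_ints(rng, n).astype(str),  # inert filler
            "quantity": _rand_ints(rng, n).astype(str),  # inert filler
        }
    )


def _split_parts(table: pd.DataFrame, n_parts: int) -> list[pd.DataFrame]:
    """Deterministically deal rows across *n_parts* files (round-robin)."""
    if n_parts == 0:
        return []
    assignment = np.arange(len(table)) % n_parts
    return [table[assignment == k].reset_index(drop=True) for k in range(n_parts)]


def _write_parts(
    out_dir: Path,
    prefix: str,
    set_number: int,
    filetype: str,
    parts: list[pd.DataFrame],
    settings: Settings,
    entries: list[FileEntry],
) -> None:
    for k, part in enumerate(parts, start=1):
        name = format_filename(prefix, set_number, filetype, k)
        write_raw_file(part, out_dir / name, settings=settings)
        entries.append(FileEntry(name, filetype, set_number, k, len(part)))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_fixture(
    out_dir: str | Path,
    n_patients: int = 12,
    patient_sets: Mapping[int, Sequence[int]] | None = None,
    parts_per_type: int | Mapping[int, int] | None = None,
    seed: int = 1,
    obs_per_patient: int = 5,
    drugs_per_patient: int = 3,
    prefix: str = DEFAULT_PREFIX,
    settings: Settings = DEFAULT_SETTINGS,
) -> FixtureManifest:
    """Write the small worked-example file tree and return its manifest.

    Parameters
    ----------
    patient_sets
        Partition of patient numbers ``1..n_patients`` into sets, as a
        mapping ``{set_number: [patient numbers]}``.  Defaults to the
        worked-example layout: patients 1–8 in set 1, 9–12 in set 2 (for
        other ``n_patients``, the first two-thirds in set 1).
    parts_per_type
        Observation/drug-issue parts per set — an int applied to every set,
        or a per-set mapping.  Defaults to 3 parts for set 1 and none for
        the others, matching the worked example where all medical-event
        files sit in set 1.
    """
    out_dir = Path(out_dir)
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    out_dir.mkdir(parents=True, exist_ok=True)

    if patient_sets is None:
        cut = min(max(1, round(n_patients * 2 / 3)), n_patients) if n_patients else 0
        if n_patients == 12:
            cut = 8
        patient_sets = {1: list(range(1, cut + 1)), 2: list(range(cut + 1, n_patients + 1))}
        patient_sets = {s: ps for s, ps in patient_sets.items() if ps or s == 1}
        if parts_per_type is None:
            parts_per_type = {1: 3}
    if parts_per_type is None:
        parts_per_type = 3

    # Validate the partition: every patient in exactly one set.
    assigned: list[int] = []
    for ps in patient_sets.values():
        assigned.extend(int(p) for p in ps)
    expected = list(range(1, n_patients + 1))
    if sorted(assigned) != expected or len(assigned) != len(set(assigned)):
        raise ValueError(
            "patient_sets must partition patients 1..n_patients: got "
            f"{sorted(assigned)}, expected {expected}"
        )

    def _n_parts(set_number: int) -> int:
        if isinstance(parts_per_type, Mapping):
            return int(parts_per_type.get(set_number, 0))
        return int(parts_per_type)

    rng = np.random.default_rng(seed)
    entries: list[FileEntry] = []
    for set_number in sorted(patient_sets):
        patids = [str(p) for p in patient_sets[set_number]]
        patient_tab = _patient_table(rng, patids)
        name = format_filename(prefix, set_number, "patient", 1)
        write_raw_file(patient_tab, out_dir / name, settings=settings)
        entries.append(FileEntry(name, "patient", set_number, 1, len(patids)))

        n_parts = _n_parts(set_number)
        n_obs = obs_per_patient * len(patids) if n_parts else 0
        obs = _observation_table(
            rng,
            rng.choice(np.array(patids, dtype=object), size=n_obs) if n_obs else np.array([], dtype=object),
            rng.choice(np.array(FIXTURE_MEDCODES, dtype=object), size=n_obs),
            _rand_dates(rng, n_obs, _SIM_DATE_START, _SIM_DATE_END),
        )
        _write_parts(out_dir, prefix, set_number, "observation", _split_parts(obs, n_parts), settings, entries)

        n_drug = drugs_per_patient * len(patids) if n_parts else 0
        drug = _drugissue_table(
            rng,
            rng.choice(np.array(patids, dtype=object), size=n_drug) if n_drug else np.array([], dtype=object),
            rng.choice(np.array(FIXTURE_PRODCODES, dtype=object), size=n_drug),
            _rand_dates(rng, n_drug, _SIM_DATE_START, _SIM_DATE_END),
        )
        _write_parts(out_dir, prefix, set_number, "drugissue", _split_parts(drug, n_parts), settings, entries)

    manifest = FixtureManifest(str(out_dir), tuple(entries), seed)
    manifest.to_json(out_dir / "manifest.json")
    return manifest


#: Background observation codes for generated studies; disjoint by
#: construction from any planted code checked in StudyRecipe validation.
_BACKGROUND_MEDCODES = tuple(f"9000000000{i:02d}" for i in range(20))
_BACKGROUND_PRODCODES = tuple(f"8000000000{i:02d}" for i in range(10))


def generate_study(
    recipe: StudyRecipe,
    out_dir: str | Path,
    settings: Settings = DEFAULT_SETTINGS,
) -> FixtureManifest:
    """Write a randomized study-scale tree plus a ground-truth sidecar.

    For each code ``c`` with prevalence ``p`` in the recipe, every patient
    independently receives (with probability ``p``) at least one observation
    carrying ``c`` dated strictly before the recipe's index date.  All other
    observations use background codes, so a patient's truth flag for ``c``
    is 1 exactly when any record of ``c`` exists.  Flags are written to
    ``truth.csv`` (columns ``patid,code,flag``) next to the raw files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    overlap = set(recipe.code_prevalences) & set(_BACKGROUND_MEDCODES)
    if overlap:
        raise ValueError(f"planted codes collide with background pool: {overlap}")

    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_patients
    patids = np.array([str(i) for i in range(1, n + 1)], dtype=object)
    set_of_patient = (np.arange(n) * recipe.n_sets // n) + 1  # contiguous blocks

    pre_index_end = (pd.Timestamp(recipe.index_date) - pd.Timedelta(days=1)).strftime(
        "%Y-%m-%d"
    )

    truth_rows: list[pd.DataFrame] = []
    planted: list[pd.DataFrame] = []
    for code in sorted(recipe.code_prevalences):
        p = recipe.code_prevalences[code]
        flags = (rng.random(n) < p).astype(int)
        truth_rows.append(pd.DataFrame({"patid": patids, "code": code, "flag": flags}))
        carriers = patids[flags == 1]
        if len(carriers):
            planted.append(
                _observation_table(
                    rng,
                    carriers,
                    np.full(len(carriers), code, dtype=object),
                    _rand_dates(rng, len(carriers), _SIM_DATE_START, pre_index_end),
                )
            )

    entries: list[FileEntry] = []
    for set_number in range(1, recipe.n_sets + 1):
        mask = set_of_patient == set_number
        set_patids = patids[mask]
        patient_tab = _patient_table(rng, list(set_patids))
        name = format_filename(recipe.prefix, set_number, "patient", 1)
        write_raw_file(patient_tab, out_dir / name, settings=settings)
        entries.append(FileEntry(name, "patient", set_number, 1, len(set_patids)))

        n_obs = int(rng.poisson(recipe.obs_per_patient * len(set_patids)))
        obs = _observation_table(
            rng,
            rng.choice(set_patids, size=n_obs),
            rng.choice(np.array(_BACKGROUND_MEDCODES, dtype=object), size=n_obs),
            _rand_dates(rng, n_obs, _SIM_DATE_START, _SIM_DATE_END),
        )
        set_planted = [t[t["patid"].isin(set_patids)] for t in planted]
        obs = pd.concat([obs, *set_planted], ignore_index=True)
        _write_parts(
            out_dir, recipe.prefix, set_number, "observation",
            _split_parts(obs, recipe.obs_files_per_set), settings, entries,
        )

        n_drug = int(rng.poisson(recipe.drugs_per_patient * len(set_patids)))
        drug = _drugissue_table(
            rng,
            rng.choice(set_patids, size=n_drug),
            rng.choice(np.array(_BACKGROUND_PRODCODES, dtype=object), size=n_drug),
            _rand_dates(rng, n_drug, _SIM_DATE_START, _SIM_DATE_END),
        )
        _write_parts(
            out_dir, recipe.prefix, set_number, "drugissue",
            _split_parts(drug, recipe.drug_files_per_set), settings, entries,
        )

    if truth_rows:
        truth = pd.concat(truth_rows, ignore_index=True)
    else:
        truth = pd.DataFrame(columns=["patid", "code", "flag"])
    truth.to_csv(out_dir / "truth.csv", index=False, lineterminator="\n")

    manifest = FixtureManifest(str(out_dir), tuple(entries), recipe.seed)
    manifest.to_json(out_dir / "manifest.json")
    return manifest
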