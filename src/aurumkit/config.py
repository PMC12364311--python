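"""Package-wide conventions.

All date-window and parsing conventions live in a single :class:`Settings`
object so that the store-backed extraction path and the raw-file oracle path
are guaranteed to apply identical rules.  Every function that depends on a
convention takes an optional ``settings`` argument defaulting to
:data:`DEFAULT_SETTINGS`; a YAML config file can override any field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

logger = logging.getLogger("aurumkit")

#: Date formats tried in order when parsing raw-file date cells.  The source
#: system writes UK-style day-first dates; ISO-8601 is accepted as well and
#: ambiguous strings resolve day-first.
DATE_FORMATS = ("%d/%m/%Y", "%Y-%m-%d")


@dataclass(frozen=True)
class Settings:
    """Conventions shared by every module.

    Parameters
    ----------
    delimiter
        Field separator of the raw ``.txt`` extract files.
    date_formats
        Formats attempted, in order, when parsing date cells.
    date_output_format
        Format used when *writing* raw files (synthetic data).
    chunk_size
        Rows per chunk when streaming raw files larger than memory.
    history_inclusive
        If True (default), an event dated exactly on the index date counts as
        history ("on or before").  Applied identically by the store-backed
        path and the brute-force raw-file oracle.
    time_until_strict
        If True (default), time-to-event search starts strictly after the
        index date, so survival times are always positive.
    height_unit_scale
        Mapping from ``numunitid`` code to a multiplicative factor applied to
        height values before computing BMI (e.g. centimetre codes map to
        0.01).  Real unit lookups are licence-gated, so this table is
        caller-configurable.
    height_cm_heuristic
        Heights above this value (metres) are assumed to be centimetres and
        divided by 100 even when their unit code is unmapped.
    """

    delimiter: str = "\t"
    date_formats: tuple[str, ...] = DATE_FORMATS
    date_output_format: str = "%d/%m/%Y"
    chunk_size: int = 1_000_000
    history_inclusive: bool = True
    time_until_strict: bool = True
    height_unit_scale: Mapping[str, float] = field(
        default_factory=lambda: {"cm": 0.01, "centimetres": 0.01, "m": 1.0}
    )
    height_cm_heuristic: float = 3.0

    def with_overrides(self, **kwargs) -> "Settings":
        return replace(self, **kwargs)


DEFAULT_SETTINGS = Settings()


def load_settings(path: str | Path) -> Settings:
    """Load a YAML config file overriding any :class:`Settings` field."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in Settings.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "date_formats" in known:
        known["date_formats"] = tuple(known["date_formats"])
    return Settings(**known)
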