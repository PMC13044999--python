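"""Temporal normalization and unit conversion shared by all extractors.

The source system stores every timestamp as a UTC ISO-8601 string; all exported
data streams are normalized to Central European Time (CET/CEST, tz database
``Europe/Berlin``).  Because the source of truth is UTC, the conversion is
one-way and ambiguous local times never arise.

The unit registry is a flat curated table (``data/units.csv``) covering the
dimensions that occur in medication and observation processing: mass (µg, mg,
g), volume (mL, L), biological activity (U, IU — treated as synonyms), and
time (s, min, h).  Compound rate units such as ``mg/h`` are handled by
converting numerator and denominator independently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timezone
from functools import lru_cache
from importlib import resources
from zoneinfo import ZoneInfo

from .errors import DimensionError, TimestampFormatError, UnknownUnitError

LOCAL_TZ = ZoneInfo("Europe/Berlin")
UTC = timezone.utc

__all__ = [
    "LOCAL_TZ",
    "LocalTimestamp",
    "UnitConversion",
    "parse_utc",
    "to_local",
    "format_local",
    "conversion_factor",
    "convert_unit",
]


# ---------------------------------------------------------------------------
# Timestamps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalTimestamp:
    """A UTC instant together with its Europe/Berlin rendering."""

    instant: datetime          # tz-aware, UTC
    local_repr: str            # ISO-8601 with explicit +01:00/+02:00 offset

    @property
    def local(self) -> datetime:
        return self.instant.astimezone(LOCAL_TZ)


def parse_utc(ts: "str | datetime") -> datetime:
    """Parse a UTC instant from an ISO-8601 string or datetime.

    Naive datetimes are interpreted as UTC (the source convention);
    tz-aware inputs are converted to UTC.
    """
    if isinstance(ts, datetime):
        if ts.tzinfo is None:
            return ts.replace(tzinfo=UTC)
        return ts.astimezone(UTC)
    if not isinstance(ts, str):
        raise TimestampFormatError(f"not a timestamp: {ts!r}")
    try:
        parsed = datetime.fromisoformat(ts.replace("Z", "+00:00"))
    except ValueError as exc:
        raise TimestampFormatError(f"unparseable timestamp: {ts!r}") from exc
    if parsed.tzinfo is None:
        parsed = parsed.replace(tzinfo=UTC)
    return parsed.astimezone(UTC)


def to_local(ts: "str | datetime") -> LocalTimestamp:
    """Convert a UTC instant to local CET/CEST time.

    The underlying instant is never changed; only the rendering offset
    (+01:00 in winter, +02:00 in summer, DST transitions included) differs.
    """
    instant = parse_utc(ts)
    local = instant.astimezone(LOCAL_TZ)
    return LocalTimestamp(instant=instant, local_repr=local.isoformat())


def format_local(ts: "str | datetime | None") -> "str | None":
    """Render a UTC instant as a local ISO-8601 string (None passes through)."""
    if ts is None:
        return None
    return to_local(ts).local_repr


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitConversion:
    from_unit: str
    to_unit: str
    factor: float


@lru_cache(maxsize=1)
def _registry() -> "dict[str, tuple[str, float]]":
    text = resources.files("pdms_etl.data").joinpath("units.csv").read_text(encoding="utf-8")
    table: dict[str, tuple[str, float]] = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["unit"]] = (row["dimension"], float(row["factor_to_base"]))
    return table


def _lookup(unit: str) -> tuple[str, float]:
    try:
        return _registry()[unit]
    except KeyError:
        raise UnknownUnitError(f"unit not in registry: {unit!r}") from None


def conversion_factor(from_unit: str, to_unit: str) -> UnitConversion:
    """Multiplicative factor taking a value in ``from_unit`` to ``to_unit``.

    Compound units of the form ``a/b`` convert numerator and denominator
    independently; simple units must share a dimension.
    """
    if "/" in from_unit or "/" in to_unit:
        if ("/" in from_unit) != ("/" in to_unit):
            raise DimensionError(f"cannot convert {from_unit!r} to {to_unit!r}")
        f_num, f_den = from_unit.split("/", 1)
        t_num, t_den = to_unit.split("/", 1)
        num = conversion_factor(f_num, t_num).factor
        den = conversion_factor(f_den, t_den).factor
        return UnitConversion(from_unit, to_unit, num / den)
    dim_from, f_from = _lookup(from_unit)
    dim_to, f_to = _lookup(to_unit)
    if dim_from != dim_to:
        raise DimensionError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return UnitConversion(from_unit, to_unit, f_from / f_to)


def convert_unit(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension."""
    if from_unit == to_unit:
        return value
    return value * conversion_factor(from_unit, to_unit).factor
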