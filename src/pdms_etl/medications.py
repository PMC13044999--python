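"""Medication concentration reconstruction and dose-rate standardization.

Medication administrations are documented in three heterogeneous formats —
a pump rate in mL/h, a total volume over an interval, or a discrete dose —
and the source rows never state the drug concentration.  The concentration is
reconstructed from the internal drug catalog (ingredient amount per diluent
volume of the standard mixture) and every record is harmonized into one of
two standardized event kinds:

* ``infusion`` — continuous application at a rate in mg/h or U/h,
* ``bolus``   — a single application of an amount in mg or U.

Rate-format records convert as ``rate = value[mL/h] × concentration``;
volume-format records are interpreted as evenly infused over their documented
interval, ``rate = value[mL] × concentration / duration[h]``; dose-format
records become boluses with the amount converted to the standard unit.
A volume record without a usable interval cannot be resolved and is routed to
a failure list, never silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .errors import CatalogError, UnresolvableRecordError
from .harmonize import convert_unit, parse_utc

__all__ = [
    "RawMedicationRecord",
    "MixtureDefinition",
    "StandardizedMedicationEvent",
    "DrugCatalog",
    "load_drug_catalog",
    "reconstruct_concentration",
    "standardize_record",
    "standardize_batch",
    "aggregate_window",
]

DOC_FORMATS = ("volume", "dose", "rate")


@dataclass(frozen=True)
class RawMedicationRecord:
    """One source medication row in whatever format the bedside pump produced."""

    record_id: str
    case_id: str
    drug_id: str
    doc_format: str            # 'volume' | 'dose' | 'rate'
    value: float
    unit: str                  # e.g. mL, mL/h, mg, µg, U
    start_ts: datetime
    end_ts: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.doc_format not in DOC_FORMATS:
            raise ValueError(f"unknown doc_format: {self.doc_format!r}")
        if self.value < 0:
            raise ValueError("medication value must be non-negative")
        object.__setattr__(self, "start_ts", parse_utc(self.start_ts))
        if self.end_ts is not None:
            object.__setattr__(self, "end_ts", parse_utc(self.end_ts))


@dataclass(frozen=True)
class MixtureDefinition:
    """Standard mixture of one drug product: ingredient amount per diluent volume."""

    drug_id: str
    ingredient: str
    ingredient_amount: float   # in amount_unit
    amount_unit: str           # mg-family or U-family
    diluent_volume: float      # mL
    standard_unit: str         # 'mg/h' or 'U/h'

    def __post_init__(self) -> None:
        if self.ingredient_amount < 0:
            raise ValueError("ingredient_amount must be non-negative")
        if self.diluent_volume <= 0:
            raise ValueError("diluent_volume must be positive")

    @property
    def standard_amount_unit(self) -> str:
        return self.standard_unit.split("/", 1)[0]  # 'mg' or 'U'


@dataclass(frozen=True)
class StandardizedMedicationEvent:
    """A harmonized medication event with a standardized amount or rate."""

    case_id: str
    ingredient: str
    kind: Literal["bolus", "infusion"]
    unit: str                       # mg | U (bolus), mg/h | U/h (infusion)
    start_ts: datetime
    end_ts: Optional[datetime] = None
    amount: Optional[float] = None  # bolus
    rate: Optional[float] = None    # infusion
    source_record_id: Optional[str] = None


class DrugCatalog:
    """Lookup of mixture definitions, keyed by drug_id with an ingredient-name
    fallback (the transparent realization of catalog-based classification)."""

    def __init__(self, mixtures: Iterable[MixtureDefinition]):
        self._by_id: dict[str, MixtureDefinition] = {}
        self._by_ingredient: dict[str, MixtureDefinition] = {}
        for mix in mixtures:
            self._by_id[mix.drug_id] = mix
            self._by_ingredient.setdefault(mix.ingredient.lower(), mix)

    def resolve(self, drug_id: str) -> MixtureDefinition:
        mix = self._by_id.get(drug_id) or self._by_ingredient.get(drug_id.lower())
        if mix is None:
            raise CatalogError(f"drug not resolvable in catalog: {drug_id!r}")
        return mix

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)


def load_drug_catalog(source: "str | Path | None" = None) -> DrugCatalog:
    """Load the drug catalog from a CSV path, or the packaged default table.

    Expected columns: drug_id, ingredient, amount, amount_unit, volume_ml,
    standard_unit.
    """
    if source is None:
        text = resources.files("pdms_etl.data").joinpath("drug_catalog.csv").read_text(
            encoding="utf-8"
        )
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    return DrugCatalog(
        MixtureDefinition(
            drug_id=r["drug_id"],
            ingredient=r["ingredient"],
            ingredient_amount=float(r["amount"]),
            amount_unit=r["amount_unit"],
            diluent_volume=float(r["volume_ml"]),
            standard_unit=r["standard_unit"],
        )
        for r in rows
    )


def reconstruct_concentration(mix: MixtureDefinition) -> float:
    """Concentration of the standard mixture, in standard-unit per mL.

    The ingredient amount is first converted to the standard mass/activity
    unit (mg or U), then divided by the diluent volume.
    """
    amount_std = convert_unit(
        mix.ingredient_amount, mix.amount_unit, mix.standard_amount_unit
    )
    return amount_std / mix.diluent_volume


def _duration_hours(start: datetime, end: Optional[datetime]) -> float:
    if end is None:
        return 0.0
    return (end - start).total_seconds() / 3600.0


def standardize_record(
    raw: RawMedicationRecord, catalog: DrugCatalog
) -> StandardizedMedicationEvent:
    """Harmonize one raw record into a standardized bolus or infusion event.

    Raises :class:`CatalogError` for unresolvable drugs and
    :class:`UnresolvableRecordError` for interval-dependent formats without a
    usable interval; batch callers route these to the failure report.
    """
    mix = catalog.resolve(raw.drug_id)
    concentration = reconstruct_concentration(mix)  # (mg|U) per mL
    std_unit = mix.standard_unit
    amount_unit = mix.standard_amount_unit

    if raw.doc_format == "dose":
        amount = convert_unit(raw.value, raw.unit, amount_unit)
        return StandardizedMedicationEvent(
            case_id=raw.case_id,
            ingredient=mix.ingredient,
            kind="bolus",
            unit=amount_unit,
            start_ts=raw.start_ts,
            end_ts=None,
            amount=amount,
            source_record_id=raw.record_id,
        )

    if raw.end_ts is None or raw.end_ts <= raw.start_ts:
        raise UnresolvableRecordError(
            f"record {raw.record_id}: {raw.doc_format}-format documentation "
            f"without a positive-length interval"
        )

    if raw.doc_format == "rate":
        value_ml_h = convert_unit(raw.value, raw.unit, "mL/h")
        rate = value_ml_h * concentration
    else:  # volume, evenly infused over the documented interval
        value_ml = convert_unit(raw.value, raw.unit, "mL")
        rate = value_ml * concentration / _duration_hours(raw.start_ts, raw.end_ts)

    return StandardizedMedicationEvent(
        case_id=raw.case_id,
        ingredient=mix.ingredient,
        kind="infusion",
        unit=std_unit,
        start_ts=raw.start_ts,
        end_ts=raw.end_ts,
        rate=rate,
        source_record_id=raw.record_id,
    )


def standardize_batch(
    records: Iterable[RawMedicationRecord], catalog: DrugCatalog
) -> "tuple[list[StandardizedMedicationEvent], list[tuple[str, str]]]":
    """Standardize a batch; returns (events, failures as (record_id, reason))."""
    events: list[StandardizedMedicationEvent] = []
    failures: list[tuple[str, str]] = []
    for raw in records:
        try:
            events.append(standardize_record(raw, catalog))
        except (CatalogError, UnresolvableRecordError) as exc:
            failures.append((raw.record_id, str(exc)))
    return events, failures


def aggregate_window(
    events: Iterable[StandardizedMedicationEvent],
    window: "tuple[datetime, datetime]",
) -> "dict[tuple[str, str], float]":
    """Total drug application per (ingredient, amount unit) within a window.

    A bolus contributes its amount if its timestamp falls inside the half-open
    window; an infusion contributes rate × overlap duration.  Totals are keyed
    by (ingredient, unit) with unit mg or U, so mass and activity never mix.
    """
    w_start, w_end = parse_utc(window[0]), parse_utc(window[1])
    if not w_start < w_end:
        raise ValueError("window start must precede window end")
    totals: dict[tuple[str, str], float] = {}
    for ev in events:
        amount_unit = ev.unit.split("/", 1)[0]
        key = (ev.ingredient, amount_unit)
        if ev.kind == "bolus":
            if w_start <= ev.start_ts < w_end and ev.amount is not None:
                totals[key] = totals.get(key, 0.0) + ev.amount
        else:
            if ev.end_ts is None or ev.rate is None:
                continue
            overlap_s = (
                min(ev.end_ts, w_end) - max(ev.start_ts, w_start)
            ).total_seconds()
            if overlap_s > 0:
                totals[key] = totals.get(key, 0.0) + ev.rate * overlap_s / 3600.0
    return totals
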