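"""Demographics and observation extraction plus source data-quality checks.

Demographics is the canonical simple extraction: exactly one output row per
case, with age derived from date of birth at admission (completed years) and
the date of birth discarded before anything leaves this module — direct
identifiers are never materialized in output rows.

Point-of-care results (e.g. blood gas analyses) additionally need
content-aware filtering: the same analyte appears under one variable id with
a specimen context marker (arterial vs. venous), so retrieval filters on
analyte identity AND context.

The quality checks are read-only probes of the source: cases mapping to more
than one patient identifier, and same-patient admission windows that overlap
(half-open ``[start, end)`` semantics — abutting windows do not overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .errors import CatalogError
from .harmonize import format_local, parse_utc
from .source_adapter import (
    DEFAULT_CHUNK_SIZE,
    SourceHandle,
    fetch_by_case_ids,
    fetch_by_ids,
)

__all__ = [
    "QualityFindings",
    "PocAnalyteSpec",
    "age_at",
    "extract_demographics",
    "extract_observations",
    "filter_poc_results",
    "check_case_patient_consistency",
    "check_admission_overlaps",
]


@dataclass(frozen=True)
class QualityFindings:
    """Findings of a source data-quality probe."""

    n_cases_checked: int
    multi_patient_cases: "tuple[str, ...]" = ()
    overlapping_admissions: "tuple[tuple[str, str], ...]" = ()
    n_skipped_incomplete: int = 0

    @property
    def multi_patient_rate(self) -> float:
        return len(self.multi_patient_cases) / max(self.n_cases_checked, 1)

    def to_dict(self) -> dict:
        return {
            "n_cases_checked": self.n_cases_checked,
            "multi_patient_cases": list(self.multi_patient_cases),
            "multi_patient_rate": self.multi_patient_rate,
            "overlapping_admissions": [list(p) for p in self.overlapping_admissions],
            "n_skipped_incomplete": self.n_skipped_incomplete,
        }


def age_at(date_of_birth: "date | str", reference: "date | str") -> int:
    """Age in completed years at a reference date."""
    dob = date.fromisoformat(date_of_birth) if isinstance(date_of_birth, str) else date_of_birth
    ref = date.fromisoformat(reference) if isinstance(reference, str) else reference
    years = ref.year - dob.year
    if (ref.month, ref.day) < (dob.month, dob.day):
        years -= 1
    return years


def extract_demographics(
    handle: SourceHandle,
    case_ids: Sequence[str],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> "list[dict]":
    """One demographics row per matched case.

    A case number that maps to several patient identifiers in the source (a
    known, rare source inconsistency) is resolved deterministically to the
    lexicographically smallest patient id, so the one-row-per-case contract
    holds regardless of upstream duplication.  Output carries derived age,
    never date of birth or name.
    """
    case_rows = fetch_by_case_ids(handle, "cases", case_ids, chunk_size)
    chosen: dict[str, dict] = {}
    for row in sorted(case_rows, key=lambda r: (r["case_id"], r["patient_id"])):
        chosen.setdefault(row["case_id"], row)
    patient_ids = sorted({r["patient_id"] for r in chosen.values()})
    patient_rows = fetch_by_ids(handle, "patients", "patient_id", patient_ids, chunk_size)
    patients = {p["patient_id"]: p for p in patient_rows}

    out: list[dict] = []
    for case_id in sorted(chosen):
        row = chosen[case_id]
        patient = patients.get(row["patient_id"], {})
        admission_local = format_local(row["admission_ts"])
        admission_date = parse_utc(row["admission_ts"]).date()
        out.append(
            {
                "case_id": case_id,
                "admission_ts": admission_local,
                "discharge_ts": format_local(row["discharge_ts"]),
                "age_at_admission": (
                    age_at(patient["date_of_birth"], admission_date)
                    if patient.get("date_of_birth")
                    else None
                ),
                "sex": patient.get("sex"),
                "ward": row["ward"],
            }
        )
    return out


def extract_observations(
    handle: SourceHandle,
    case_ids: Sequence[str],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> "list[dict]":
    """All observation rows for the requested cases, timestamps localized."""
    rows = fetch_by_case_ids(handle, "observations", case_ids, chunk_size)
    return [
        {
            "case_id": r["case_id"],
            "variable_id": r["variable_id"],
            "value": r["value"],
            "unit": r["unit"],
            "ts": format_local(r["ts"]),
            "context": r["context"],
        }
        for r in rows
    ]


@dataclass(frozen=True)
class PocAnalyteSpec:
    """Analyte identity plus specimen-context predicate for POC filtering.

    ``context`` may be a literal marker value (e.g. ``"arterial"``) or a
    predicate over the row's context field; the exact encoding of specimen
    context is vendor-specific, hence configurable.
    """

    variable_ids: "frozenset[str]"
    context: "str | Callable[[Optional[str]], bool] | None" = None

    def matches_context(self, value: Optional[str]) -> bool:
        if self.context is None:
            return True
        if callable(self.context):
            return bool(self.context(value))
        return value == self.context


def filter_poc_results(
    rows: Iterable[Mapping],
    analyte_spec: PocAnalyteSpec,
    catalog: "Optional[set[str]]" = None,
) -> "list[dict]":
    """Content-aware filter: keep rows matching analyte identity AND context.

    A pure subset operation — relative row order is preserved.  If a variable
    catalog is supplied, every spec variable must be cataloged.
    """
    if catalog is not None:
        unknown = set(analyte_spec.variable_ids) - set(catalog)
        if unknown:
            raise CatalogError(f"uncataloged variables in analyte spec: {sorted(unknown)}")
    return [
        dict(r)
        for r in rows
        if r["variable_id"] in analyte_spec.variable_ids
        and analyte_spec.matches_context(r.get("context"))
    ]


def check_case_patient_consistency(
    handle: SourceHandle,
    case_ids: Sequence[str],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> QualityFindings:
    """Find case numbers mapping to more than one patient identifier."""
    rows = fetch_by_case_ids(handle, "cases", case_ids, chunk_size)
    mapping: dict[str, set] = {}
    for row in rows:
        mapping.setdefault(row["case_id"], set()).add(row["patient_id"])
    multi = tuple(sorted(c for c, pats in mapping.items() if len(pats) > 1))
    return QualityFindings(
        n_cases_checked=len(mapping),
        multi_patient_cases=multi,
    )


def check_admission_overlaps(
    case_windows: Iterable["tuple[str, str, Optional[object], Optional[object]]"],
) -> QualityFindings:
    """Report same-patient admission windows with positive-length intersection.

    Input: (case_id, patient_id, admission, discharge) tuples; windows missing
    either timestamp are skipped and counted.  Half-open semantics: windows
    that merely abut are not overlapping.
    """
    complete: dict[str, list[tuple[datetime, datetime, str]]] = {}
    n_checked = 0
    n_skipped = 0
    for case_id, patient_id, start, end in case_windows:
        if start is None or end is None:
            n_skipped += 1
            continue
        n_checked += 1
        complete.setdefault(patient_id, []).append(
            (parse_utc(start), parse_utc(end), case_id)
        )
    overlaps: list[tuple[str, str]] = []
    for windows in complete.values():
        windows.sort()
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                a_start, a_end, a_case = windows[i]
                b_start, b_end, b_case = windows[j]
                if b_start >= a_end:
                    break  # sorted: no later window can overlap window i
                if min(a_end, b_end) > max(a_start, b_start):
                    overlaps.append(tuple(sorted((a_case, b_case))))
    return QualityFindings(
        n_cases_checked=n_checked,
        overlapping_admissions=tuple(sorted(set(overlaps))),
        n_skipped_incomplete=n_skipped,
    )
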