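"""Seeded synthetic PDMS fixture with injected documentation pathologies.

The operational source this package targets is a transaction-oriented,
denormalized ICU documentation database that cannot be shared.  This module
generates a self-contained stand-in: an embedded single-file SQLite database
with tables ``patients``, ``cases``, ``bed_occupancy``, ``observations``,
``medication_records``, ``therapy_records``, ``drug_catalog`` and
``variable_catalog``, all timestamps stored as UTC ISO-8601 strings at second
resolution, plus a :class:`GroundTruth` object holding the hidden true
episodes, rates and identity map so that every downstream stage is testable
by recovery.

Injected pathologies mirror the documentation behaviour of real bedside
systems:

* therapy end times go missing (``p_missing_end``) — the generator places
  missing termination markers only where an end is recoverable in principle:
  on non-terminal reverification fragments (a later entry for the same
  intervention supersedes them) or on terminal records of therapies that ran
  until the end of bed occupancy.  A charted mid-stay stop implies the stop
  was documented; missing markers arise at discharge/handover.
* reverification of an ongoing therapy appends overlapping/abutting records
  for the same continuous intervention (``p_reverify``);
* rarely, one case number maps to multiple patient identifiers
  (``p_case_patient_conflict``), injected as a duplicate case row pointing at
  a phantom patient so admission windows stay non-overlapping per patient;
* medication rows document volume, dose, or rate with no concentration — the
  concentration exists only in the drug catalog;
* a fraction of cases is still admitted at extraction time (open admission
  window, open bed occupancy, possibly truly ongoing therapies).

Identical config + seed produces a byte-identical fixture.
"""

from __future__ import annotations

import json
import math
import random
import sqlite3
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Callable, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .medications import load_drug_catalog
from .source_adapter import SourceHandle, connect_readonly
from .therapy_episodes import DEVICE_TYPES, RawTherapyRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TrueEpisode",
    "TrueRate",
    "TrueBolus",
    "generate_fixture",
    "inject_pathologies",
    "groundtruth_path",
]

WARDS = ("ICU1", "ICU2", "PACU")

#: clinically realistic infusion-rate and bolus-amount ranges per catalog drug,
#: in the drug's standard unit (mg or U)
DRUG_PROFILES: "dict[str, tuple[tuple[float, float], tuple[float, float]]]" = {
    "D001": ((0.1, 5.0), (0.005, 0.02)),      # norepinephrine
    "D002": ((50.0, 300.0), (50.0, 200.0)),   # propofol
    "D003": ((500.0, 2000.0), (2000.0, 5000.0)),  # heparin
    "D004": ((0.5, 10.0), (2.0, 10.0)),       # insulin
    "D005": ((0.05, 0.5), (0.05, 0.2)),       # fentanyl
    "D006": ((2.0, 20.0), (2.0, 10.0)),       # midazolam
    "D007": ((1.0, 10.0), (10.0, 40.0)),      # furosemide
    "D008": ((10.0, 50.0), (150.0, 300.0)),   # amiodarone
}

VARIABLE_CATALOG = (
    ("VAR_HR", "heart_rate", "/min", "vital"),
    ("VAR_MAP", "mean_arterial_pressure", "mmHg", "vital"),
    ("VAR_SPO2", "spo2", "%", "vital"),
    ("VAR_TEMP", "temperature", "°C", "vital"),
    ("VAR_LACT", "lactate", "mmol/L", "poc"),
    ("VAR_PO2", "po2", "mmHg", "poc"),
)

_VITAL_RANGES = {
    "VAR_HR": (40.0, 160.0),
    "VAR_MAP": (50.0, 120.0),
    "VAR_SPO2": (88.0, 100.0),
    "VAR_TEMP": (35.0, 39.5),
}
_POC_RANGES = {"VAR_LACT": (0.4, 8.0), "VAR_PO2": (60.0, 300.0)}

_SCHEMA = """
CREATE TABLE patients (
    patient_id TEXT PRIMARY KEY, name TEXT, date_of_birth TEXT, sex TEXT);
CREATE TABLE cases (
    case_id TEXT, patient_id TEXT, admission_ts TEXT, discharge_ts TEXT,
    ward TEXT, or_start_ts TEXT, or_end_ts TEXT);
CREATE TABLE bed_occupancy (
    case_id TEXT, start_ts TEXT, end_ts TEXT);
CREATE TABLE observations (
    case_id TEXT, variable_id TEXT, value REAL, unit TEXT, ts TEXT, context TEXT);
CREATE TABLE medication_records (
    record_id TEXT, case_id TEXT, drug_id TEXT, doc_format TEXT,
    value REAL, unit TEXT, start_ts TEXT, end_ts TEXT);
CREATE TABLE therapy_records (
    record_id TEXT, case_id TEXT, device_type TEXT, start_ts TEXT, end_ts TEXT);
CREATE TABLE drug_catalog (
    drug_id TEXT PRIMARY KEY, ingredient TEXT, amount REAL, amount_unit TEXT,
    volume_ml REAL, standard_unit TEXT);
CREATE TABLE variable_catalog (
    variable_id TEXT PRIMARY KEY, name TEXT, unit TEXT, kind TEXT);
"""


class SyntheticConfig(BaseModel):
    """Study conditions of the synthetic cohort.

    Defaults reproduce the documented source characteristics: ~266.5
    medication events per case, one case→multiple-patient conflict per 1838
    cases, and ~8% of admission windows still open at extraction time.
    """

    n_cases: int = Field(ge=1)
    seed: int = 0
    p_missing_end: float = Field(default=0.3, ge=0.0, le=1.0)
    p_reverify: float = Field(default=0.5, ge=0.0, le=1.0)
    mean_drug_events_per_case: float = Field(default=266.5, gt=0.0)
    p_case_patient_conflict: float = Field(default=1.0 / 1838.0, ge=0.0, le=1.0)
    date_range: "tuple[date, date]" = (date(2024, 1, 1), date(2024, 6, 30))
    p_open_case: float = Field(default=0.08, ge=0.0, le=1.0)
    p_or_interval: float = Field(default=0.8, ge=0.0, le=1.0)
    mean_vitals_per_case: float = Field(default=40.0, ge=0.0)
    mean_poc_per_case: float = Field(default=8.0, ge=0.0)

    @model_validator(mode="after")
    def _ordered_dates(self) -> "SyntheticConfig":
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start must not exceed its end")
        return self


@dataclass(frozen=True)
class TrueEpisode:
    case_id: str
    device_type: str
    start_ts: str                 # UTC ISO-8601
    end_ts: Optional[str]         # None = truly ongoing at extraction time


@dataclass(frozen=True)
class TrueRate:
    case_id: str
    ingredient: str
    start_ts: str
    end_ts: str
    rate: float                   # in standard unit per hour
    unit: str                     # 'mg/h' or 'U/h'


@dataclass(frozen=True)
class TrueBolus:
    case_id: str
    ingredient: str
    ts: str
    amount: float
    unit: str                     # 'mg' or 'U'


@dataclass
class GroundTruth:
    """Hidden truth of the generated fixture, the oracle for recovery tests."""

    true_episodes: "list[TrueEpisode]" = field(default_factory=list)
    true_rates: "list[TrueRate]" = field(default_factory=list)
    true_boluses: "list[TrueBolus]" = field(default_factory=list)
    identity_map: "dict[str, str]" = field(default_factory=dict)
    conflicted_cases: "set[str]" = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_episodes": [vars(e) for e in self.true_episodes],
                "true_rates": [vars(r) for r in self.true_rates],
                "true_boluses": [vars(b) for b in self.true_boluses],
                "identity_map": self.identity_map,
                "conflicted_cases": sorted(self.conflicted_cases),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            true_episodes=[TrueEpisode(**e) for e in raw["true_episodes"]],
            true_rates=[TrueRate(**r) for r in raw["true_rates"]],
            true_boluses=[TrueBolus(**b) for b in raw["true_boluses"]],
            identity_map=raw["identity_map"],
            conflicted_cases=set(raw["conflicted_cases"]),
        )

    def save(self, path: "str | Path") -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: "str | Path") -> "GroundTruth":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def groundtruth_path(fixture_path: "str | Path") -> Path:
    p = Path(fixture_path)
    return p.with_name(p.name + ".groundtruth.json")


def _iso(dt: datetime) -> str:
    return dt.replace(microsecond=0).isoformat()


def _count(rng: random.Random, mean: float) -> int:
    """Approximately Poisson event count (normal approximation, clipped)."""
    if mean <= 0:
        return 0
    return max(0, round(rng.gauss(mean, math.sqrt(mean))))


# ---------------------------------------------------------------------------
# Pathology injection
# ---------------------------------------------------------------------------

def inject_pathologies(
    records: Sequence[RawTherapyRecord],
    config: SyntheticConfig,
    rng: random.Random,
    end_nullable: "Callable[[RawTherapyRecord], bool] | None" = None,
) -> "list[RawTherapyRecord]":
    """Fragment well-formed therapy records the way bedside documentation does.

    For each input record, reverification entries covering the tail of the
    same interval are appended with probability ``p_reverify`` (repeatable,
    capped at three); afterwards each record's end timestamp is nulled with
    probability ``p_missing_end``.  ``end_nullable`` optionally restricts
    which records may lose their end (the fixture generator passes the
    recoverability predicate); by default all records are eligible.
    """
    fragmented: list[RawTherapyRecord] = []
    counter = 0
    for rec in records:
        fragmented.append(rec)
        n_extra = 0
        while n_extra < 3 and rng.random() < config.p_reverify:
            n_extra += 1
            counter += 1
            if rec.end_ts is not None and rec.end_ts > rec.start_ts:
                span = (rec.end_ts - rec.start_ts).total_seconds()
                offset = rng.uniform(0.1, 0.9) * span
                new_start = rec.start_ts + timedelta(seconds=round(offset))
                new_end: Optional[datetime] = rec.end_ts
            else:
                new_start = rec.start_ts + timedelta(
                    seconds=round(rng.uniform(600, 4 * 3600))
                )
                new_end = None
            fragmented.append(
                RawTherapyRecord(
                    record_id=f"{rec.record_id}_rv{counter}",
                    case_id=rec.case_id,
                    device_type=rec.device_type,
                    start_ts=new_start,
                    end_ts=new_end,
                )
            )
    out: list[RawTherapyRecord] = []
    for rec in fragmented:
        nullable = end_nullable is None or end_nullable(rec)
        if rec.end_ts is not None and nullable and rng.random() < config.p_missing_end:
            rec = RawTherapyRecord(
                record_id=rec.record_id,
                case_id=rec.case_id,
                device_type=rec.device_type,
                start_ts=rec.start_ts,
                end_ts=None,
            )
        out.append(rec)
    return out


def _fragment_episode(
    rng: random.Random,
    config: SyntheticConfig,
    case_id: str,
    device: str,
    start: datetime,
    end: Optional[datetime],
    occupancy_end: Optional[datetime],
    record_counter: "list[int]",
) -> "list[tuple]":
    """Raw therapy rows for one true episode, with recoverable pathologies.

    Returns (record_id, case_id, device, start_iso, end_iso_or_None) tuples.
    Missing ends are placed only where recoverable: non-terminal fragments
    (superseded by a later entry) or a terminal record whose true end
    coincides with a closed bed-occupancy end.
    """
    def next_id() -> str:
        record_counter[0] += 1
        return f"T{record_counter[0]:08d}"

    if end is None:
        # truly ongoing therapy: last documentation carries no end by nature
        rows = [(next_id(), case_id, device, _iso(start), None)]
        n_extra = 0
        while n_extra < 3 and rng.random() < config.p_reverify:
            n_extra += 1
            re_start = start + timedelta(
                seconds=round(rng.uniform(600, 12 * 3600))
            )
            rows.append((next_id(), case_id, device, _iso(re_start), None))
        return rows

    # choose split points for reverification fragments
    n_splits = 0
    while n_splits < 3 and rng.random() < config.p_reverify:
        n_splits += 1
    span_s = (end - start).total_seconds()
    splits = sorted(
        start + timedelta(seconds=round(rng.uniform(0.1, 0.9) * span_s))
        for _ in range(n_splits)
    )
    bounds = [start, *splits, end]
    rows = []
    for i in range(len(bounds) - 1):
        frag_start = bounds[i]
        terminal = i == len(bounds) - 2
        if terminal:
            ends_at_occupancy = occupancy_end is not None and end == occupancy_end
            if ends_at_occupancy and rng.random() < config.p_missing_end:
                frag_end: Optional[datetime] = None
            else:
                frag_end = end
        else:
            if rng.random() < config.p_missing_end:
                frag_end = None  # open fragment, superseded by the next entry
            else:
                # overlap or abut the next fragment, never leaving a gap
                nxt = bounds[i + 1]
                max_overlap_s = min(1800.0, (end - nxt).total_seconds())
                overlap = rng.uniform(0.0, max(max_overlap_s, 0.0))
                frag_end = nxt + timedelta(seconds=round(overlap))
        rows.append(
            (
                next_id(),
                case_id,
                device,
                _iso(frag_start),
                None if frag_end is None else _iso(frag_end),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixture(
    config: SyntheticConfig, path: "str | Path"
) -> "tuple[SourceHandle, GroundTruth]":
    """Generate the relational fixture and its ground truth.

    Writes a SQLite database at ``path`` and the ground truth JSON next to it
    (``<path>.groundtruth.json``), then returns a read-only handle plus the
    in-memory :class:`GroundTruth`.  Admission windows per patient are
    non-overlapping by construction; regenerating with an identical config is
    byte-identical.
    """
    if not isinstance(config, SyntheticConfig):
        try:
            config = SyntheticConfig(**dict(config))
        except Exception as exc:
            raise ConfigurationError(f"invalid synthetic config: {exc}") from exc
    path = Path(path)
    rng = random.Random(config.seed)
    truth = GroundTruth()
    catalog = load_drug_catalog()
    mixtures = {m.drug_id: m for m in catalog}
    drug_ids = sorted(mixtures)

    range_start = datetime(
        config.date_range[0].year, config.date_range[0].month,
        config.date_range[0].day, tzinfo=timezone.utc,
    )
    range_end = datetime(
        config.date_range[1].year, config.date_range[1].month,
        config.date_range[1].day, 23, 59, 59, tzinfo=timezone.utc,
    )
    span_s = (range_end - range_start).total_seconds()

    patients, cases, occupancy = [], [], []
    observations, med_rows, therapy_rows = [], [], []
    patient_counter = 0
    phantom_counter = 0
    med_counter = [0]
    therapy_counter = [0]
    # patients discharged early enough to be readmitted: (patient_id, last discharge)
    readmittable: list[tuple[str, datetime]] = []

    for i in range(1, config.n_cases + 1):
        case_id = f"C{i:06d}"
        los = timedelta(seconds=round(rng.uniform(1.0, 14.0) * 86400))

        reuse = None
        if readmittable and rng.random() < 0.10:
            candidate = readmittable.pop(0)
            gap = timedelta(seconds=round(rng.uniform(1.0, 30.0) * 86400))
            admission = candidate[1] + gap
            if admission + los <= range_end:
                reuse = candidate
        if reuse is not None:
            patient_id = reuse[0]
            admission = reuse[1] + gap
        else:
            patient_counter += 1
            patient_id = f"P{patient_counter:06d}"
            admission = range_start + timedelta(
                seconds=round(rng.uniform(0.0, max(span_s - los.total_seconds(), 1.0)))
            )
            age_years = rng.uniform(18.0, 95.0)
            dob = (admission - timedelta(days=age_years * 365.25)).date()
            sex = rng.choices(("f", "m", "d"), weights=(49, 49, 2))[0]
            patients.append(
                (patient_id, f"Surname{patient_counter} Given{patient_counter}",
                 dob.isoformat(), sex)
            )
        virtual_end = admission + los
        open_case = rng.random() < config.p_open_case
        discharge = None if open_case else virtual_end
        if not open_case:
            readmittable.append((patient_id, virtual_end))
        truth.identity_map[case_id] = patient_id
        ward = rng.choice(WARDS)

        # operating-room interval (denormalized onto the case row)
        or_start = or_end = None
        if rng.random() < config.p_or_interval and los >= timedelta(hours=6):
            offset = rng.uniform(0.05, 0.3) * los.total_seconds()
            o_start = admission + timedelta(seconds=round(offset))
            dur = timedelta(seconds=round(rng.uniform(1.0, 6.0) * 3600))
            o_end = min(o_start + dur, virtual_end)
            or_start, or_end = _iso(o_start), _iso(o_end)

        cases.append(
            (case_id, patient_id, _iso(admission),
             None if discharge is None else _iso(discharge), ward, or_start, or_end)
        )
        occupancy.append(
            (case_id, _iso(admission), None if discharge is None else _iso(discharge))
        )

        # identifier-inconsistency pathology: duplicate case row, phantom patient
        if rng.random() < config.p_case_patient_conflict:
            phantom_counter += 1
            phantom_id = f"PX{phantom_counter:04d}"
            patients.append(
                (phantom_id, f"Phantom{phantom_counter} Conflict{phantom_counter}",
                 "1970-01-01", "d")
            )
            cases.append(
                (case_id, phantom_id, _iso(admission),
                 None if discharge is None else _iso(discharge), ward,
                 or_start, or_end)
            )
            truth.conflicted_cases.add(case_id)

        def stay_instant(margin_s: float = 0.0) -> datetime:
            lo, hi = 0.0, max(los.total_seconds() - margin_s, 1.0)
            return admission + timedelta(seconds=round(rng.uniform(lo, hi)))

        # vitals and point-of-care observations
        for _ in range(_count(rng, config.mean_vitals_per_case)):
            var = rng.choice(tuple(_VITAL_RANGES))
            lo, hi = _VITAL_RANGES[var]
            unit = next(v[2] for v in VARIABLE_CATALOG if v[0] == var)
            observations.append(
                (case_id, var, round(rng.uniform(lo, hi), 1), unit,
                 _iso(stay_instant()), None)
            )
        for _ in range(_count(rng, config.mean_poc_per_case)):
            var = rng.choice(tuple(_POC_RANGES))
            lo, hi = _POC_RANGES[var]
            unit = next(v[2] for v in VARIABLE_CATALOG if v[0] == var)
            context = "arterial" if rng.random() < 0.7 else "venous"
            observations.append(
                (case_id, var, round(rng.uniform(lo, hi), 2), unit,
                 _iso(stay_instant()), context)
            )

        # medication events
        for _ in range(_count(rng, config.mean_drug_events_per_case)):
            drug_id = rng.choice(drug_ids)
            mix = mixtures[drug_id]
            rate_range, bolus_range = DRUG_PROFILES[drug_id]
            concentration = (mix.ingredient_amount / mix.diluent_volume)
            doc_format = rng.choice(("volume", "dose", "rate"))
            med_counter[0] += 1
            record_id = f"M{med_counter[0]:08d}"
            if doc_format == "dose":
                amount = round(rng.uniform(*bolus_range), 4)
                ts = stay_instant()
                if mix.standard_unit == "mg/h" and amount < 1.0:
                    value, unit = round(amount * 1000, 4), "µg"
                else:
                    value, unit = amount, mix.standard_amount_unit
                med_rows.append(
                    (record_id, case_id, drug_id, "dose", value, unit, _iso(ts), None)
                )
                truth.true_boluses.append(
                    TrueBolus(case_id, mix.ingredient, _iso(ts), amount,
                              mix.standard_amount_unit)
                )
            else:
                dur_h = rng.uniform(0.5, 12.0)
                start = stay_instant(margin_s=1800.0)
                end = min(start + timedelta(seconds=round(dur_h * 3600)), virtual_end)
                if end <= start:
                    end = start + timedelta(minutes=30)
                rate = round(rng.uniform(*rate_range), 4)
                if doc_format == "rate":
                    value, unit = rate / concentration, "mL/h"
                else:
                    hours = (end - start).total_seconds() / 3600.0
                    value, unit = rate * hours / concentration, "mL"
                med_rows.append(
                    (record_id, case_id, drug_id, doc_format, value, unit,
                     _iso(start), _iso(end))
                )
                truth.true_rates.append(
                    TrueRate(case_id, mix.ingredient, _iso(start), _iso(end),
                             rate, mix.standard_unit)
                )

        # therapy/device episodes
        if los >= timedelta(hours=12):
            for device in DEVICE_TYPES:
                if rng.random() >= 0.25:
                    continue
                ep_start = admission + timedelta(
                    seconds=round(rng.uniform(0.0, 0.3) * los.total_seconds())
                )
                runs_to_discharge = rng.random() < 0.5
                if runs_to_discharge:
                    ep_end = None if open_case else virtual_end
                else:
                    max_dur = max((virtual_end - ep_start).total_seconds() - 5 * 3600,
                                  4 * 3600)
                    dur = rng.uniform(4 * 3600, max(max_dur, 4 * 3600 + 1))
                    ep_end = min(ep_start + timedelta(seconds=round(dur)),
                                 virtual_end)
                truth.true_episodes.append(
                    TrueEpisode(case_id, device, _iso(ep_start),
                                None if ep_end is None else _iso(ep_end))
                )
                therapy_rows.extend(
                    _fragment_episode(
                        rng, config, case_id, device, ep_start, ep_end,
                        discharge, therapy_counter,
                    )
                )
                # occasional second, clearly separated episode
                if (ep_end is not None and not runs_to_discharge
                        and rng.random() < 0.05):
                    gap = timedelta(hours=rng.uniform(4.0, 8.0))
                    start2 = ep_end + gap
                    if start2 + timedelta(hours=2) < virtual_end:
                        end2 = min(
                            start2 + timedelta(seconds=round(rng.uniform(2, 10) * 3600)),
                            virtual_end,
                        )
                        truth.true_episodes.append(
                            TrueEpisode(case_id, device, _iso(start2), _iso(end2))
                        )
                        therapy_rows.extend(
                            _fragment_episode(
                                rng, config, case_id, device, start2, end2,
                                discharge, therapy_counter,
                            )
                        )

    # write the embedded database
    if path.exists():
        path.unlink()
    gt_file = groundtruth_path(path)
    try:
        conn = sqlite3.connect(path)
    except sqlite3.Error as exc:
        raise OSError(f"fixture path not writable: {path}") from exc
    with conn:
        conn.executescript(_SCHEMA)
        conn.executemany("INSERT INTO patients VALUES (?,?,?,?)", patients)
        conn.executemany("INSERT INTO cases VALUES (?,?,?,?,?,?,?)", cases)
        conn.executemany("INSERT INTO bed_occupancy VALUES (?,?,?)", occupancy)
        conn.executemany("INSERT INTO observations VALUES (?,?,?,?,?,?)", observations)
        conn.executemany(
            "INSERT INTO medication_records VALUES (?,?,?,?,?,?,?,?)", med_rows
        )
        conn.executemany("INSERT INTO therapy_records VALUES (?,?,?,?,?)", therapy_rows)
        conn.executemany(
            "INSERT INTO drug_catalog VALUES (?,?,?,?,?,?)",
            [
                (m.drug_id, m.ingredient, m.ingredient_amount, m.amount_unit,
                 m.diluent_volume, m.standard_unit)
                for m in (mixtures[d] for d in drug_ids)
            ],
        )
        conn.executemany(
            "INSERT INTO variable_catalog VALUES (?,?,?,?)", VARIABLE_CATALOG
        )
    conn.close()
    truth.save(gt_file)
    return connect_readonly(path), truth
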