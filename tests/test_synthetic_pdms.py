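"""Synthetic fixture generator: determinism, pathologies, conservation."""

import hashlib
import random
from datetime import datetime, timezone

import pytest
from pydantic import ValidationError

from pdms_etl.harmonize import parse_utc
from pdms_etl.synthetic_pdms import (
    GroundTruth,
    SyntheticConfig,
    generate_fixture,
    groundtruth_path,
    inject_pathologies,
)
from pdms_etl.therapy_episodes import RawTherapyRecord


def _small(seed=1, **overrides):
    defaults = dict(n_cases=15, seed=seed, mean_drug_events_per_case=10.0)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def test_identical_config_and_seed_gives_byte_identical_fixture(tmp_path):
    for name in ("a.db", "b.db"):
        handle, _ = generate_fixture(_small(), tmp_path / name)
        handle.close()
    digest = lambda p: hashlib.sha256((tmp_path / p).read_bytes()).hexdigest()
    assert digest("a.db") == digest("b.db")
    assert (
        groundtruth_path(tmp_path / "a.db").read_text()
        == groundtruth_path(tmp_path / "b.db").read_text()
    )


def test_different_seed_changes_fixture(tmp_path):
    h1, t1 = generate_fixture(_small(seed=1), tmp_path / "a.db")
    h2, t2 = generate_fixture(_small(seed=2), tmp_path / "b.db")
    h1.close(), h2.close()
    assert t1.to_json() != t2.to_json()


def test_invalid_config_rejected():
    with pytest.raises(ValidationError):
        SyntheticConfig(n_cases=0, seed=1)
    with pytest.raises(ValidationError):
        SyntheticConfig(n_cases=5, seed=1, p_missing_end=1.5)


def test_all_stored_timestamps_are_utc(clean_fixture):
    handle, *_ = clean_fixture
    for table, col in [("cases", "admission_ts"), ("therapy_records", "start_ts"),
                       ("medication_records", "start_ts"), ("observations", "ts")]:
        rows = handle.execute(f"SELECT {col} AS ts FROM {table} WHERE {col} IS NOT NULL LIMIT 20")
        assert rows
        for r in rows:
            parsed = datetime.fromisoformat(r["ts"])
            assert parsed.utcoffset().total_seconds() == 0


def test_pathology_free_case_maps_records_one_to_one(tmp_path):
    cfg = _small(p_missing_end=0.0, p_reverify=0.0, p_open_case=0.0,
                 p_case_patient_conflict=0.0)
    handle, truth = generate_fixture(cfg, tmp_path / "c.db")
    rows = handle.execute("SELECT * FROM therapy_records")
    handle.close()
    assert len(rows) == len(truth.true_episodes)
    got = sorted((r["case_id"], r["device_type"], r["start_ts"], r["end_ts"]) for r in rows)
    want = sorted((e.case_id, e.device_type, e.start_ts, e.end_ts) for e in truth.true_episodes)
    assert got == want


def test_groundtruth_roundtrips_and_sits_next_to_fixture(tmp_path):
    handle, truth = generate_fixture(_small(), tmp_path / "d.db")
    handle.close()
    loaded = GroundTruth.load(groundtruth_path(tmp_path / "d.db"))
    assert loaded.to_json() == truth.to_json()
    assert set(loaded.identity_map) >= {e.case_id for e in loaded.true_episodes}


def test_true_episodes_disjoint_per_case_device(pathological_fixture):
    _, truth, *_ = pathological_fixture
    groups = {}
    for e in truth.true_episodes:
        groups.setdefault((e.case_id, e.device_type), []).append(e)
    for eps in groups.values():
        eps.sort(key=lambda e: e.start_ts)
        for a, b in zip(eps, eps[1:]):
            assert a.end_ts is not None and parse_utc(a.end_ts) <= parse_utc(b.start_ts)


def test_admission_windows_never_overlap_per_patient(pathological_fixture):
    handle, *_ = pathological_fixture
    rows = handle.execute(
        "SELECT patient_id, admission_ts, discharge_ts FROM cases "
        "WHERE discharge_ts IS NOT NULL ORDER BY patient_id, admission_ts"
    )
    windows = {}
    for r in rows:
        windows.setdefault(r["patient_id"], []).append(
            (parse_utc(r["admission_ts"]), parse_utc(r["discharge_ts"]))
        )
    for spans in windows.values():
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2, "same-patient admissions must not overlap"


def test_conflict_pathology_is_countable_and_recorded(tmp_path):
    cfg = _small(n_cases=40, p_case_patient_conflict=0.5)
    handle, truth = generate_fixture(cfg, tmp_path / "e.db")
    rows = handle.execute(
        "SELECT case_id, COUNT(DISTINCT patient_id) AS n FROM cases "
        "GROUP BY case_id HAVING n > 1"
    )
    handle.close()
    assert {r["case_id"] for r in rows} == truth.conflicted_cases
    assert truth.conflicted_cases <= set(truth.identity_map)
    assert truth.conflicted_cases, "p=0.5 over 40 cases should conflict at least once"


def test_concentrations_absent_from_medication_records(clean_fixture):
    handle, *_ = clean_fixture
    columns = handle.table_columns("medication_records")
    assert "concentration" not in columns
    assert set(columns) == {"record_id", "case_id", "drug_id", "doc_format",
                            "value", "unit", "start_ts", "end_ts"}
    catalog_cols = handle.table_columns("drug_catalog")
    assert {"amount", "volume_ml"} <= set(catalog_cols)


# --- inject_pathologies (standalone operation) -----------------------------

def _episode_record(start="2024-01-01T10:00:00+00:00", end="2024-01-01T14:00:00+00:00"):
    return RawTherapyRecord("T1", "C1", "ECMO", start, end)


def test_inject_all_missing_ends():
    cfg = _small(p_missing_end=1.0, p_reverify=0.0)
    out = inject_pathologies([_episode_record()], cfg, random.Random(0))
    assert all(r.end_ts is None for r in out)


def test_inject_nothing_is_identity():
    cfg = _small(p_missing_end=0.0, p_reverify=0.0)
    records = [_episode_record()]
    assert inject_pathologies(records, cfg, random.Random(0)) == records


def test_reverification_union_covers_true_episode():
    cfg = _small(p_missing_end=0.0, p_reverify=1.0)
    rec = _episode_record()
    out = inject_pathologies([rec], cfg, random.Random(3))
    assert len(out) >= 2
    assert min(r.start_ts for r in out) == rec.start_ts
    assert max(r.end_ts for r in out if r.end_ts) == rec.end_ts
    # every fragment stays inside the true episode
    for r in out:
        assert rec.start_ts <= r.start_ts
        assert r.end_ts is None or r.end_ts <= rec.end_ts


def test_injection_always_preserves_start_coverage():
    cfg = _small(p_missing_end=0.7, p_reverify=0.7)
    rng = random.Random(9)
    for trial in range(50):
        rec = _episode_record()
        out = inject_pathologies([rec], cfg, rng)
        assert min(r.start_ts for r in out) == rec.start_ts
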