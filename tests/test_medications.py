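"""Concentration reconstruction, rate standardization, window aggregation."""

import math
from datetime import datetime, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdms_etl.errors import CatalogError, UnresolvableRecordError
from pdms_etl.harmonize import parse_utc
from pdms_etl.medications import (
    DrugCatalog,
    MixtureDefinition,
    RawMedicationRecord,
    StandardizedMedicationEvent,
    aggregate_window,
    load_drug_catalog,
    reconstruct_concentration,
    standardize_batch,
    standardize_record,
)

T0 = "2024-01-01T10:00:00+00:00"
T2 = "2024-01-01T12:00:00+00:00"
T4 = "2024-01-01T14:00:00+00:00"


def _mix(amount=5.0, unit="mg", volume=50.0):
    return MixtureDefinition("DX", "testdrug", amount, unit, volume, "mg/h")


@pytest.mark.parametrize(
    ("amount", "unit", "volume", "expected"),
    [
        (5, "mg", 50, 0.1),
        (500, "U", 50, 10.0),
        (0, "mg", 50, 0.0),        # degenerate but legal placebo mixture
        (500, "µg", 50, 0.01),     # amount converted to standard unit first
    ],
)
def test_reconstruct_concentration(amount, unit, volume, expected):
    mix = MixtureDefinition(
        "DX", "x", amount, unit, volume, "U/h" if unit == "U" else "mg/h"
    )
    assert reconstruct_concentration(mix) == pytest.approx(expected)


def test_zero_volume_rejected_at_construction():
    with pytest.raises(ValueError):
        MixtureDefinition("DX", "x", 5, "mg", 0, "mg/h")


def _catalog():
    return DrugCatalog([_mix()])


def test_rate_format_becomes_infusion():
    raw = RawMedicationRecord("M1", "C1", "DX", "rate", 6.0, "mL/h", T0, T4)
    ev = standardize_record(raw, _catalog())
    assert (ev.kind, ev.unit) == ("infusion", "mg/h")
    assert ev.rate == pytest.approx(0.6)  # 6 mL/h x 0.1 mg/mL


def test_volume_format_spread_over_interval():
    raw = RawMedicationRecord("M2", "C1", "DX", "volume", 30.0, "mL", T0, T2)
    ev = standardize_record(raw, _catalog())
    assert ev.kind == "infusion"
    assert ev.rate == pytest.approx(1.5)  # 30 mL x 0.1 mg/mL / 2 h


def test_dose_format_becomes_bolus_in_standard_unit():
    raw = RawMedicationRecord("M3", "C1", "DX", "dose", 500.0, "µg", T0, None)
    ev = standardize_record(raw, _catalog())
    assert (ev.kind, ev.unit) == ("bolus", "mg")
    assert ev.amount == pytest.approx(0.5)


def test_unknown_drug_is_catalog_error():
    raw = RawMedicationRecord("M4", "C1", "NOPE", "rate", 6.0, "mL/h", T0, T4)
    with pytest.raises(CatalogError):
        standardize_record(raw, _catalog())


def test_ingredient_name_fallback_resolves():
    raw = RawMedicationRecord("M5", "C1", "testdrug", "rate", 6.0, "mL/h", T0, T4)
    assert standardize_record(raw, _catalog()).ingredient == "testdrug"


def test_volume_without_interval_routed_to_failures_not_dropped():
    raw = RawMedicationRecord("M6", "C1", "DX", "volume", 30.0, "mL", T0, None)
    with pytest.raises(UnresolvableRecordError):
        standardize_record(raw, _catalog())
    events, failures = standardize_batch([raw], _catalog())
    assert events == []
    assert failures[0][0] == "M6"


def test_packaged_catalog_units_are_dimensionally_sound():
    for mix in load_drug_catalog():
        amount_dim_activity = mix.amount_unit in ("U", "IU")
        assert mix.standard_unit.endswith("/h")
        assert (mix.standard_unit == "U/h") == amount_dim_activity


def _bolus(ts, amount):
    return StandardizedMedicationEvent(
        case_id="C1", ingredient="x", kind="bolus", unit="mg",
        start_ts=parse_utc(ts), amount=amount,
    )


def _infusion(start, end, rate, ingredient="x"):
    return StandardizedMedicationEvent(
        case_id="C1", ingredient=ingredient, kind="infusion", unit="mg/h",
        start_ts=parse_utc(start), end_ts=parse_utc(end), rate=rate,
    )


def test_bolus_window_membership_sum():
    events = [
        _bolus("2024-01-01T10:00:00Z", 5),
        _bolus("2024-01-01T10:30:00Z", 3),
        _bolus("2024-01-01T13:00:00Z", 2),
    ]
    window = (parse_utc("2024-01-01T09:45:00Z"), parse_utc("2024-01-01T12:00:00Z"))
    assert aggregate_window(events, window) == {("x", "mg"): pytest.approx(8.0)}


def test_infusion_contributes_rate_times_overlap():
    events = [_infusion("2024-01-01T10:00:00Z", "2024-01-01T14:00:00Z", 2.0)]
    window = (parse_utc("2024-01-01T11:00:00Z"), parse_utc("2024-01-01T13:00:00Z"))
    assert aggregate_window(events, window) == {("x", "mg"): pytest.approx(4.0)}


def test_disjoint_window_contributes_nothing():
    events = [_infusion("2024-01-01T10:00:00Z", "2024-01-01T11:00:00Z", 2.0)]
    window = (parse_utc("2024-01-02T00:00:00Z"), parse_utc("2024-01-02T01:00:00Z"))
    assert aggregate_window(events, window) == {}


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    split=st.floats(min_value=0.01, max_value=23.99),
    starts=st.lists(
        st.tuples(st.floats(0, 24), st.floats(0.1, 12), st.floats(0.01, 50)),
        min_size=1, max_size=8,
    ),
)
def test_aggregation_additive_over_window_partition(split, starts):
    """aggregate[a,b) + aggregate[b,c) == aggregate[a,c) for infusions."""
    from datetime import timedelta

    base = datetime(2024, 1, 1, tzinfo=timezone.utc)
    events = [
        _infusion(base + timedelta(hours=s), base + timedelta(hours=s + d), rate)
        for s, d, rate in starts
    ]
    a, b, c = base, base + timedelta(hours=split), base + timedelta(hours=24)
    left = aggregate_window(events, (a, b))
    right = aggregate_window(events, (b, c))
    whole = aggregate_window(events, (a, c))
    keys = set(left) | set(right) | set(whole)
    for key in keys:
        assert left.get(key, 0) + right.get(key, 0) == pytest.approx(
            whole.get(key, 0), rel=1e-9, abs=1e-12
        )


def test_rates_recovered_exactly_on_pathology_free_fixture(clean_fixture):
    handle, truth, *_ = clean_fixture
    rows = handle.execute("SELECT * FROM medication_records")
    records = [
        RawMedicationRecord(r["record_id"], r["case_id"], r["drug_id"],
                            r["doc_format"], r["value"], r["unit"],
                            r["start_ts"], r["end_ts"])
        for r in rows
    ]
    from pdms_etl.pipeline import _load_db_catalog

    events, failures = standardize_batch(records, _load_db_catalog(handle))
    assert failures == []
    got = sorted(
        (e.case_id, e.ingredient, e.start_ts, e.unit, e.rate)
        for e in events if e.kind == "infusion"
    )
    want = sorted(
        (r.case_id, r.ingredient, parse_utc(r.start_ts), r.unit, r.rate)
        for r in truth.true_rates
    )
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert g[:4] == w[:4]
        assert math.isclose(g[4], w[4], rel_tol=1e-9)
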