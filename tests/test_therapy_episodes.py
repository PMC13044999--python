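"""Episode merging, end-time inference, and ground-truth recovery."""

import random
from datetime import datetime, timedelta, timezone

import pytest

from pdms_etl.errors import GroupingError
from pdms_etl.harmonize import parse_utc
from pdms_etl.therapy_episodes import (
    BedOccupancyInterval,
    RawTherapyRecord,
    TherapyEpisode,
    infer_end_times,
    merge_records,
    reconstruct_episodes,
)


def _t(hours: float) -> datetime:
    return datetime(2024, 1, 1, tzinfo=timezone.utc) + timedelta(hours=hours)


def _rec(rid, start_h, end_h, case="C1", device="ECMO"):
    return RawTherapyRecord(
        rid, case, device, _t(start_h), None if end_h is None else _t(end_h)
    )


# --- independent naive oracle ----------------------------------------------

def _oracle_merge(records, tol):
    """Naive chronological clustering recomputed from full cluster contents."""
    def key(r):
        return (r.start_ts, r.end_ts is None, r.end_ts or r.start_ts)

    def cluster_state(cluster):
        max_start = max(x.start_ts for x in cluster)
        terminal_open = any(
            x.start_ts == max_start and x.end_ts is None for x in cluster
        )
        closed = [x.end_ts for x in cluster if x.end_ts is not None]
        return max_start, terminal_open, (max(closed) if closed else None)

    clusters = []
    for r in sorted(records, key=key):
        placed = False
        if clusters:
            _, terminal_open, max_end = cluster_state(clusters[-1])
            if terminal_open or (max_end is not None and r.start_ts <= max_end + tol):
                clusters[-1].append(r)
                placed = True
        if not placed:
            clusters.append([r])
    episodes = []
    for cluster in clusters:
        _, terminal_open, max_end = cluster_state(cluster)
        episodes.append(
            (
                min(x.start_ts for x in cluster),
                None if terminal_open else max_end,
                len(cluster),
            )
        )
    return episodes


def _oracle_infer(provisional, occupancy):
    out = []
    for start, end, n in provisional:
        if end is not None:
            out.append((start, end, n, False, False))
            continue
        enclosing = [
            o for o in occupancy
            if o.start_ts <= start and (o.end_ts is None or start < o.end_ts)
        ]
        if not enclosing or enclosing[0].end_ts is None:
            out.append((start, None, n, False, True))
        else:
            out.append((start, enclosing[0].end_ts, n, True, False))
    return out


# --- merge_records ----------------------------------------------------------

def test_overlapping_records_merge_to_union():
    eps = merge_records([_rec("a", 10, 11), _rec("b", 10.5, 12)])
    assert len(eps) == 1
    assert (eps[0].start_ts, eps[0].end_ts, eps[0].n_source_records) == (_t(10), _t(12), 2)


def test_gap_tolerance_decides_episode_split():
    records = [_rec("a", 10, 11), _rec("b", 11.5, 12)]
    assert len(merge_records(records, timedelta(minutes=60))) == 1
    merged = merge_records(records, timedelta(minutes=60))[0]
    assert (merged.start_ts, merged.end_ts) == (_t(10), _t(12))
    assert len(merge_records(records, timedelta(minutes=15))) == 2


def test_open_record_absorbed_by_later_reverification():
    eps = merge_records([_rec("a", 10, None), _rec("b", 12, 14)])
    assert len(eps) == 1
    assert (eps[0].start_ts, eps[0].end_ts, eps[0].n_source_records) == (_t(10), _t(14), 2)


def test_terminal_open_record_leaves_episode_unresolved():
    eps = merge_records([_rec("a", 10, 12), _rec("b", 11, None)])
    assert len(eps) == 1
    assert eps[0].end_ts is None and eps[0].open_terminal
    assert eps[0].max_documented_end == _t(12)


def test_mixed_groups_rejected():
    with pytest.raises(GroupingError):
        merge_records([_rec("a", 10, 11), _rec("b", 10, 11, device="IABP")])


def test_empty_input_empty_output():
    assert merge_records([]) == []
    assert reconstruct_episodes([], []) == []


# --- infer_end_times --------------------------------------------------------

def _provisional(start_h, end_h, open_terminal=None):
    eps = merge_records([_rec("x", start_h, end_h)])
    return eps


def test_missing_end_inferred_from_closed_occupancy():
    occ = [BedOccupancyInterval("C1", _t(8), _t(14))]
    (ep,) = infer_end_times(_provisional(10, None), occ)
    assert (ep.end_ts, ep.end_inferred, ep.ongoing) == (_t(14), True, False)


def test_open_occupancy_marks_episode_ongoing():
    occ = [BedOccupancyInterval("C1", _t(8), None)]
    (ep,) = infer_end_times(_provisional(10, None), occ)
    assert ep.end_ts is None and ep.ongoing and not ep.end_inferred


def test_documented_end_passes_through_unchanged():
    occ = [BedOccupancyInterval("C1", _t(8), _t(20))]
    (ep,) = infer_end_times(_provisional(10, 12), occ)
    assert (ep.end_ts, ep.end_inferred, ep.ongoing) == (_t(12), False, False)


def test_inference_never_shortens_documented_contributor_end():
    # terminal record open, but an earlier contributor documents an end
    # beyond the occupancy end: the documented end is authoritative
    provisional = merge_records([_rec("a", 10, 16), _rec("b", 11, None)])
    occ = [BedOccupancyInterval("C1", _t(8), _t(14))]
    (ep,) = infer_end_times(provisional, occ)
    assert ep.end_ts == _t(16) and ep.end_inferred


def test_orphan_episode_retained_and_flagged():
    occ = [BedOccupancyInterval("C1", _t(50), _t(60))]
    with pytest.warns(UserWarning):
        (ep,) = infer_end_times(_provisional(10, None), occ)
    assert ep.orphan and ep.ongoing


# --- reconstruct_episodes: properties and recovery --------------------------

def _random_instance(rng):
    n = rng.randint(1, 12)
    records = []
    for i in range(n):
        start = rng.uniform(0, 100)
        if rng.random() < 0.3:
            end = None
        else:
            end = start + rng.uniform(0, 20)
        records.append(_rec(f"r{i}", start, end))
    if rng.random() < 0.5:
        occ = [BedOccupancyInterval("C1", _t(-10), _t(200))]
    else:
        occ = [BedOccupancyInterval("C1", _t(-10), None)]
    tol = timedelta(hours=rng.choice([0, 0.5, 1, 2, 5]))
    return records, occ, tol


def oracle_equivalence_trials(n_trials: int, seed: int = 20240301) -> None:
    rng = random.Random(seed)
    for _ in range(n_trials):
        records, occ, tol = _random_instance(rng)
        got = [
            (e.start_ts, e.end_ts, e.n_source_records, e.end_inferred, e.ongoing)
            for e in reconstruct_episodes(records, occ, tol)
        ]
        want = _oracle_infer(_oracle_merge(records, tol), occ)
        assert got == want, f"divergence on {records} tol={tol}"


def test_matches_naive_oracle_on_random_instances():
    oracle_equivalence_trials(300)


def test_output_episodes_disjoint_and_cover_closed_inputs():
    rng = random.Random(7)
    for _ in range(100):
        records, occ, tol = _random_instance(rng)
        episodes = reconstruct_episodes(records, occ, tol)
        episodes.sort(key=lambda e: e.start_ts)
        for a, b in zip(episodes, episodes[1:]):
            assert a.end_ts is None or a.end_ts <= b.start_ts
        # coverage: every closed input interval lies inside some episode
        for r in records:
            if r.end_ts is None:
                continue
            assert any(
                e.start_ts <= r.start_ts
                and (e.end_ts is None or r.end_ts <= e.end_ts)
                for e in episodes
            )


def test_reconstruction_is_idempotent():
    rng = random.Random(13)
    for _ in range(100):
        records, occ, tol = _random_instance(rng)
        first = reconstruct_episodes(records, occ, tol)
        as_records = [
            RawTherapyRecord(f"e{i}", e.case_id, e.device_type, e.start_ts,
                             None if e.ongoing else e.end_ts)
            for i, e in enumerate(first)
        ]
        second = reconstruct_episodes(as_records, occ, tol)
        assert [(e.start_ts, e.end_ts, e.ongoing) for e in second] == [
            (e.start_ts, e.end_ts, e.ongoing) for e in first
        ]


def _recover(handle, truth):
    records = [
        RawTherapyRecord(r["record_id"], r["case_id"], r["device_type"],
                         r["start_ts"], r["end_ts"])
        for r in handle.execute("SELECT * FROM therapy_records")
    ]
    occupancy = [
        BedOccupancyInterval(r["case_id"], r["start_ts"], r["end_ts"])
        for r in handle.execute("SELECT * FROM bed_occupancy")
    ]
    got = sorted(
        (e.case_id, e.device_type, e.start_ts, e.end_ts)
        for e in reconstruct_episodes(records, occupancy)
    )
    want = sorted(
        (e.case_id, e.device_type, parse_utc(e.start_ts),
         None if e.end_ts is None else parse_utc(e.end_ts))
        for e in truth.true_episodes
    )
    return got, want


def test_exact_recovery_on_pathology_free_fixture(clean_fixture):
    handle, truth, *_ = clean_fixture
    got, want = _recover(handle, truth)
    assert got == want


def test_exact_recovery_under_default_pathologies(pathological_fixture):
    """Reverified, end-stripped records still reconstruct the true episodes
    exactly: every missing end in the fixture is recoverable in principle."""
    handle, truth, *_ = pathological_fixture
    got, want = _recover(handle, truth)
    assert got == want
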