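"""Reconstruction of continuous therapy/device episodes.

Organ-support devices (ECMO, dialysis, microaxial pumps, IABP) are documented
as intervals, but two documentation pathologies fragment them: end times are
frequently missing, and reverification of an ongoing therapy produces an
additional record for the same continuous intervention.  This module rejoins
the fragments and infers missing end times from bed occupancy:

* Records of one (case, device) group are swept in chronological order.  Two
  records belong to the same episode iff their intervals overlap, abut, or are
  separated by a gap of at most ``gap_tolerance``; an open-ended record (null
  end) absorbs the next later record of the group — the later entry is read as
  a reverification that supersedes the open one.  An episode whose
  latest-starting contributor is open remains unterminated after merging.

* A merged episode with no end is then cross-referenced against the case's
  bed occupancy: if the occupancy interval containing the episode start has
  ended, the therapy cannot have outlived the stay, so the occupancy end is
  taken as the inferred episode end (never shortening a documented end).  If
  the bed is still occupied, the therapy is flagged ``ongoing``.

All intervals use half-open ``[start, end)`` semantics: abutting intervals do
not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

from .errors import GroupingError
from .harmonize import parse_utc

DEFAULT_GAP_TOLERANCE = timedelta(minutes=60)

DEVICE_TYPES = ("ECMO", "dialysis", "microaxial_pump", "IABP")

__all__ = [
    "DEFAULT_GAP_TOLERANCE",
    "DEVICE_TYPES",
    "RawTherapyRecord",
    "BedOccupancyInterval",
    "ProvisionalEpisode",
    "TherapyEpisode",
    "merge_records",
    "infer_end_times",
    "reconstruct_episodes",
]


@dataclass(frozen=True)
class RawTherapyRecord:
    """One source row of device/therapy interval documentation."""

    record_id: str
    case_id: str
    device_type: str
    start_ts: datetime
    end_ts: Optional[datetime] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_ts", parse_utc(self.start_ts))
        if self.end_ts is not None:
            end = parse_utc(self.end_ts)
            if end < self.start_ts:
                raise ValueError(
                    f"record {self.record_id}: end_ts before start_ts"
                )
            object.__setattr__(self, "end_ts", end)


@dataclass(frozen=True)
class BedOccupancyInterval:
    case_id: str
    start_ts: datetime
    end_ts: Optional[datetime] = None  # null = bed still occupied

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_ts", parse_utc(self.start_ts))
        if self.end_ts is not None:
            object.__setattr__(self, "end_ts", parse_utc(self.end_ts))

    def contains(self, instant: datetime) -> bool:
        if instant < self.start_ts:
            return False
        return self.end_ts is None or instant < self.end_ts


@dataclass(frozen=True)
class ProvisionalEpisode:
    """Merged episode before end-time inference (end may be unresolved)."""

    case_id: str
    device_type: str
    start_ts: datetime
    end_ts: Optional[datetime]
    n_source_records: int
    source_record_ids: "tuple[str, ...]"
    open_terminal: bool  # latest-starting contributor had no end
    max_documented_end: Optional[datetime] = None  # max closed contributor end


@dataclass(frozen=True)
class TherapyEpisode:
    """A reconstructed continuous episode of device support."""

    case_id: str
    device_type: str
    start_ts: datetime
    end_ts: Optional[datetime]
    end_inferred: bool
    ongoing: bool
    n_source_records: int
    source_record_ids: "tuple[str, ...]" = ()
    orphan: bool = False  # start outside every occupancy interval

    @property
    def duration(self) -> Optional[timedelta]:
        if self.end_ts is None:
            return None
        return self.end_ts - self.start_ts


def merge_records(
    records: Sequence[RawTherapyRecord],
    gap_tolerance: timedelta = DEFAULT_GAP_TOLERANCE,
) -> "list[ProvisionalEpisode]":
    """Rejoin fragmented interval records of one (case, device) group.

    Sweep in (start, end) order keeping, per growing episode, the maximum
    documented end and whether the latest-starting contributor is open.  The
    next record joins the episode if the episode is awaiting a reverification
    (open terminal) or starts within ``gap_tolerance`` of the documented end.
    Episode start is the minimum start; the end is the maximum documented end,
    or null when the terminal contributor is open (to be inferred later).
    """
    if gap_tolerance < timedelta(0):
        raise ValueError("gap_tolerance must be non-negative")
    if not records:
        return []
    groups = {(r.case_id, r.device_type) for r in records}
    if len(groups) > 1:
        raise GroupingError(f"merge_records got mixed groups: {sorted(groups)}")
    case_id, device_type = next(iter(groups))

    def sort_key(r: RawTherapyRecord):
        # open records sort after closed ones at equal start: an open
        # reverification at the same instant leaves the episode unterminated
        return (r.start_ts, r.end_ts is None, r.end_ts or r.start_ts)

    episodes: list[ProvisionalEpisode] = []
    cur: Optional[dict] = None
    for rec in sorted(records, key=sort_key):
        if cur is None:
            joins = False
        elif cur["open_terminal"]:
            joins = True  # open record absorbs the next later record
        else:
            joins = rec.start_ts <= cur["max_end"] + gap_tolerance
        if not joins:
            if cur is not None:
                episodes.append(_finish(cur, case_id, device_type))
            cur = {
                "start": rec.start_ts,
                "max_end": rec.end_ts,
                "open_terminal": rec.end_ts is None,
                "last_start": rec.start_ts,
                "ids": [rec.record_id],
            }
            continue
        assert cur is not None
        cur["ids"].append(rec.record_id)
        if rec.end_ts is not None:
            cur["max_end"] = (
                rec.end_ts if cur["max_end"] is None else max(cur["max_end"], rec.end_ts)
            )
        if rec.start_ts > cur["last_start"]:
            cur["open_terminal"] = rec.end_ts is None
            cur["last_start"] = rec.start_ts
        elif rec.end_ts is None:
            cur["open_terminal"] = True  # tie on start: open wins
    if cur is not None:
        episodes.append(_finish(cur, case_id, device_type))
    return episodes


def _finish(state: dict, case_id: str, device_type: str) -> ProvisionalEpisode:
    open_terminal = state["open_terminal"]
    return ProvisionalEpisode(
        case_id=case_id,
        device_type=device_type,
        start_ts=state["start"],
        end_ts=None if open_terminal else state["max_end"],
        n_source_records=len(state["ids"]),
        source_record_ids=tuple(state["ids"]),
        open_terminal=open_terminal,
        max_documented_end=state["max_end"],
    )


def infer_end_times(
    episodes: Sequence[ProvisionalEpisode],
    occupancy: Sequence[BedOccupancyInterval],
) -> "list[TherapyEpisode]":
    """Resolve unterminated episodes against bed occupancy.

    The occupancy interval containing the episode start decides: a closed
    occupancy supplies the inferred end (clamped to never fall below a
    documented contributor end); an open occupancy marks the episode ongoing.
    Episodes starting outside every occupancy interval are retained but
    flagged as orphans, with a warning.
    """
    by_case: dict[str, list[BedOccupancyInterval]] = {}
    for interval in occupancy:
        by_case.setdefault(interval.case_id, []).append(interval)

    out: list[TherapyEpisode] = []
    for ep in episodes:
        enclosing = next(
            (o for o in by_case.get(ep.case_id, []) if o.contains(ep.start_ts)), None
        )
        orphan = enclosing is None
        if orphan:
            warnings.warn(
                f"therapy episode for case {ep.case_id} starting {ep.start_ts} "
                f"lies outside all bed occupancy intervals",
                stacklevel=2,
            )
        if ep.end_ts is not None:
            end, inferred, ongoing = ep.end_ts, False, False
        elif enclosing is None or enclosing.end_ts is None:
            end, inferred, ongoing = None, False, True
        else:
            # documented contributor ends are authoritative: never shorten
            documented = ep.max_documented_end
            end = enclosing.end_ts if documented is None else max(enclosing.end_ts, documented)
            inferred, ongoing = True, False
        out.append(
            TherapyEpisode(
                case_id=ep.case_id,
                device_type=ep.device_type,
                start_ts=ep.start_ts,
                end_ts=end,
                end_inferred=inferred,
                ongoing=ongoing,
                n_source_records=ep.n_source_records,
                source_record_ids=ep.source_record_ids,
                orphan=orphan,
            )
        )
    return out


def reconstruct_episodes(
    records: Iterable[RawTherapyRecord],
    occupancy: Sequence[BedOccupancyInterval],
    gap_tolerance: timedelta = DEFAULT_GAP_TOLERANCE,
) -> "list[TherapyEpisode]":
    """Full reconstruction: group by (case, device) → merge → infer ends.

    Output is sorted by (case_id, device_type, start) and episodes of one
    group are pairwise disjoint under half-open semantics.
    """
    grouped: dict[tuple, list[RawTherapyRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.case_id, rec.device_type), []).append(rec)
    episodes: list[TherapyEpisode] = []
    for key in sorted(grouped):
        provisional = merge_records(grouped[key], gap_tolerance)
        episodes.extend(infer_end_times(provisional, occupancy))
    episodes.sort(key=lambda e: (e.case_id, e.device_type, e.start_ts))
    return episodes
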