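"""Directional crossing-event reconstruction from two-sensor read streams.

A departure is the sensor pattern (A, B, B); an arrival is (B, A, A).
The event is timestamped at the *middle* read of its triple.  A complete
departure-then-arrival series is the five-read pattern A, B, B, A, A:
the trailing B of the departure doubles as the leading B of the arrival.
The scanner therefore allows the last read of a matched triple to serve
as the first read of the next triple, but never rescans reads it has
already passed.

Matching is per tag, greedy, left to right.  Reads that never take part
in a matched triple are tallied, not silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Literal, Sequence

import pandas as pd

from dronetrack.rfid_io import TagRead

DEPARTURE = "departure"
ARRIVAL = "arrival"

# sensor patterns, in read order
_DEPARTURE_PATTERN = ("A", "B", "B")
_ARRIVAL_PATTERN = ("B", "A", "A")


@dataclass(frozen=True)
class CrossingEvent:
    """A reconstructed hive crossing (timestamp = middle read of the triple)."""

    tag_id: str
    kind: Literal["departure", "arrival"]
    timestamp: datetime
    read_refs: tuple[int, ...] = ()
    inferred: bool = False


@dataclass
class MatchReport:
    """Accounting of how the scanner consumed the read stream."""

    n_reads_total: int = 0
    n_reads_consumed: int = 0
    n_reads_unmatched: int = 0
    n_inconsistent_transitions: int = 0
    n_reads_debounced: int = 0

    def __add__(self, other: "MatchReport") -> "MatchReport":
        return MatchReport(
            self.n_reads_total + other.n_reads_total,
            self.n_reads_consumed + other.n_reads_consumed,
            self.n_reads_unmatched + other.n_reads_unmatched,
            self.n_inconsistent_transitions + other.n_inconsistent_transitions,
            self.n_reads_debounced + other.n_reads_debounced,
        )


def is_morning(event: CrossingEvent | datetime, cutoff_hour: int = 12) -> bool:
    """True iff the event's clock time falls in [00:00, cutoff).

    The morning/afternoon split is at 12:00 noon: an event at 11:59:59 is
    morning, one at exactly 12:00:00 is not.
    """
    ts = event.timestamp if isinstance(event, CrossingEvent) else event
    return ts.hour < cutoff_hour


def _debounce(indices: list[int], reads: Sequence[TagRead], debounce_s: float) -> tuple[list[int], int]:
    """Collapse same-sensor repeats closer than debounce_s; keep the first."""
    if debounce_s <= 0:
        return indices, 0
    kept: list[int] = []
    dropped = 0
    for idx in indices:
        if kept:
            prev = reads[kept[-1]]
            cur = reads[idx]
            if cur.sensor == prev.sensor and (cur.timestamp - prev.timestamp).total_seconds() <= debounce_s:
                dropped += 1
                continue
        kept.append(idx)
    return kept, dropped


def _scan_tag(
    indices: list[int],
    reads: Sequence[TagRead],
    lenient: bool,
) -> tuple[list[CrossingEvent], set[int]]:
    """Greedy overlap-allowed scan of one tag's reads; returns events + consumed set."""
    events: list[CrossingEvent] = []
    consumed: set[int] = set()
    n = len(indices)
    i = 0
    while i <= n - 3:
        window = indices[i : i + 3]
        sensors = tuple(reads[j].sensor for j in window)
        if sensors == _DEPARTURE_PATTERN:
            kind = DEPARTURE
        elif sensors == _ARRIVAL_PATTERN:
            kind = ARRIVAL
        else:
            i += 1
            continue
        events.append(
            CrossingEvent(
                tag_id=reads[window[0]].tag_id,
                kind=kind,
                timestamp=reads[window[1]].timestamp,
                read_refs=tuple(window),
            )
        )
        consumed.update(window)
        i += 2  # trailing read may open the next triple

    if lenient:
        # Recover departures whose closing B was lost: an unmatched (A, B)
        # immediately preceding a matched arrival's opening B is read as a
        # departure timestamped at its B read.
        arrival_starts = {ev.read_refs[0] for ev in events if ev.kind == ARRIVAL}
        pos = {idx: k for k, idx in enumerate(indices)}
        extra: list[CrossingEvent] = []
        for start in sorted(arrival_starts):
            k = pos[start]
            if k < 2:
                continue
            a, b = indices[k - 2], indices[k - 1]
            if a in consumed or b in consumed:
                continue
            if reads[a].sensor == "A" and reads[b].sensor == "B":
                extra.append(
                    CrossingEvent(
                        tag_id=reads[b].tag_id,
                        kind=DEPARTURE,
                        timestamp=reads[b].timestamp,
                        read_refs=(a, b, start),
                        inferred=True,
                    )
                )
                consumed.update((a, b))
        events.extend(extra)
        events.sort(key=lambda ev: ev.timestamp)

    return events, consumed


def detect_events(
    reads: Sequence[TagRead],
    mode: Literal["strict", "lenient"] = "strict",
    debounce_s: float = 0.0,
) -> tuple[list[CrossingEvent], MatchReport]:
    """Reconstruct departure/arrival events from a sorted read stream.

    Parameters
    ----------
    reads
        Tag reads; within each tag they must be in chronological order
        (any interleaving of tags is fine).  Out-of-order input is a hard
        error, never silently reordered.
    mode
        ``"strict"`` applies the grammar only; ``"lenient"`` additionally
        infers departures with a lost closing read (flagged ``inferred``).
    debounce_s
        Collapse same-tag same-sensor repeats within this many seconds
        before matching.  Default 0 (off): the grammar's own double-B /
        double-A signature is a same-sensor repeat, so any nonzero value
        must stay below the intra-triple read gap.

    Returns
    -------
    (events, report)
        Events sorted by (tag_id, timestamp); a :class:`MatchReport` with
        ``n_reads_consumed + n_reads_unmatched == len(reads)`` (debounced
        reads count as unmatched).
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    if debounce_s < 0:
        raise ValueError("debounce_s must be >= 0")

    by_tag: dict[str, list[int]] = {}
    for i, read in enumerate(reads):
        by_tag.setdefault(read.tag_id, []).append(i)

    for tag, idxs in by_tag.items():
        times = [reads[i].timestamp for i in idxs]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"reads for tag {tag!r} are not sorted by time")

    all_events: list[CrossingEvent] = []
    report = MatchReport(n_reads_total=len(reads))
    for tag in sorted(by_tag):
        idxs, n_dropped = _debounce(by_tag[tag], reads, debounce_s)
        events, consumed = _scan_tag(idxs, reads, lenient=(mode == "lenient"))
        report.n_reads_debounced += n_dropped
        report.n_reads_consumed += len(consumed)
        report.n_reads_unmatched += len(by_tag[tag]) - len(consumed)
        for prev, cur in zip(events, events[1:]):
            if prev.kind == cur.kind:
                report.n_inconsistent_transitions += 1
        all_events.extend(events)

    all_events.sort(key=lambda ev: (ev.tag_id, ev.timestamp))
    return all_events, report


def events_frame(events: Sequence[CrossingEvent]) -> pd.DataFrame:
    """Tabulate events for CSV output."""
    return pd.DataFrame(
        {
            "tag_id": [e.tag_id for e in events],
            "kind": [e.kind for e in events],
            "timestamp": [e.timestamp for e in events],
            "inferred": [e.inferred for e in events],
        }
    )


def events_from_frame(frame: pd.DataFrame) -> list[CrossingEvent]:
    """Rebuild event records from a table written by :func:`events_frame`."""
    inferred = frame["inferred"] if "inferred" in frame.columns else [False] * len(frame)
    return [
        CrossingEvent(
            tag_id=str(t),
            kind=str(k),
            timestamp=pd.Timestamp(ts).to_pydatetime(),
            inferred=bool(f),
        )
        for t, k, ts, f in zip(frame["tag_id"], frame["kind"], frame["timestamp"], inferred)
    ]
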