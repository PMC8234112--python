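"""Per-drone, per-hour and per-day activity analytics.

A "flight" is a completed departure->arrival pair (an uncensored outside
span).  A final departure with no return is reported separately as a
censored departure, and drones whose tag never produced a read are
carried in the cohort report rather than in per-drone summaries.
Flights are attributed to the calendar date of their departure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from dronetrack.behavior import INSIDE, OUTSIDE, BehaviorLabel, Span
from dronetrack.rfid_io import TagRead

DURATION_CLASSES = ("under_3min", "3_to_10min", "10_to_60min", "over_60min")

#: departure-time group windows, clock hours, half-open [start, end)
DEFAULT_GROUP_WINDOWS: dict[str, tuple[float, float]] = {
    "dawn": (2.0, 4.0),
    "early_morning": (5.0, 8.0),
    "midday": (10.0, 13.0),
    "late_afternoon": (16.0, 18.0),
}

DAY_S = 86400.0


def duration_class(duration_s: float) -> str:
    """Bin a flight duration into the four reporting classes."""
    if duration_s <= 180.0:
        return "under_3min"
    if duration_s <= 600.0:
        return "3_to_10min"
    if duration_s <= 3600.0:
        return "10_to_60min"
    return "over_60min"


def _span_days(duration_s: float) -> int:
    return int(duration_s // DAY_S) + 1


@dataclass
class CohortReport:
    """Tag-level accounting over the whole tagged cohort."""

    n_tagged: int
    n_never_detected: int
    n_single_read: int

    @property
    def pct_never_detected(self) -> float:
        return 100.0 * self.n_never_detected / self.n_tagged

    @property
    def pct_single_read(self) -> float:
        return 100.0 * self.n_single_read / self.n_tagged


@dataclass
class DroneSummary:
    tag_id: str
    n_flights_completed: int = 0
    n_censored_departures: int = 0
    n_reads_total: int = 0
    first_seen: Optional[datetime] = None
    last_seen: Optional[datetime] = None
    morning_departures: int = 0
    afternoon_departures: int = 0
    active_both_periods: bool = False
    category_counts: dict[str, int] = field(default_factory=dict)
    max_inside_days: int = 0
    max_outside_days: int = 0


def cohort_report(reads: Sequence[TagRead], tagged_ids: Sequence[str]) -> CohortReport:
    """Never-detected / single-read tallies over the full tag roster.

    ``tagged_ids`` is the roster of every tag deployed; tags absent from
    the read stream are the never-detected group.
    """
    if not tagged_ids:
        raise ValueError("tagged_ids must be nonempty")
    counts = Counter(r.tag_id for r in reads)
    never = sum(1 for t in tagged_ids if counts.get(t, 0) == 0)
    single = sum(1 for t in tagged_ids if counts.get(t, 0) == 1)
    return CohortReport(n_tagged=len(tagged_ids), n_never_detected=never, n_single_read=single)


def summarize_drones(
    spans: Sequence[Span],
    labels: Sequence[BehaviorLabel],
    reads: Optional[Sequence[TagRead]] = None,
    morning_cutoff_hour: int = 12,
) -> list[DroneSummary]:
    """One summary per tag appearing in the span stream.

    Departures are the start events of non-left-censored outside spans;
    morning + afternoon departures therefore always equal the total
    departure count.
    """
    if len(spans) != len(labels):
        raise ValueError("spans and labels must be aligned")
    read_counts: Counter[str] = Counter()
    read_first: dict[str, datetime] = {}
    read_last: dict[str, datetime] = {}
    if reads is not None:
        for r in reads:
            read_counts[r.tag_id] += 1
            if r.tag_id not in read_first or r.timestamp < read_first[r.tag_id]:
                read_first[r.tag_id] = r.timestamp
            if r.tag_id not in read_last or r.timestamp > read_last[r.tag_id]:
                read_last[r.tag_id] = r.timestamp

    out: dict[str, DroneSummary] = {}
    for span, label in sorted(
        zip(spans, labels), key=lambda pair: (pair[0].tag_id, pair[0].start or datetime.min)
    ):
        s = out.setdefault(span.tag_id, DroneSummary(tag_id=span.tag_id))
        s.category_counts[label.category] = s.category_counts.get(label.category, 0) + 1
        if span.location == OUTSIDE:
            if span.censored == "none":
                s.n_flights_completed += 1
                if span.duration_s is not None:
                    s.max_outside_days = max(s.max_outside_days, _span_days(span.duration_s))
            if span.censored == "right":
                s.n_censored_departures += 1
            if span.censored != "left" and span.start is not None:
                if span.start.hour < morning_cutoff_hour:
                    s.morning_departures += 1
                else:
                    s.afternoon_departures += 1
        elif span.location == INSIDE and span.censored == "none" and span.duration_s is not None:
            s.max_inside_days = max(s.max_inside_days, _span_days(span.duration_s))
        for t in (span.start, span.end):
            if t is None:
                continue
            if s.first_seen is None or t < s.first_seen:
                s.first_seen = t
            if s.last_seen is None or t > s.last_seen:
                s.last_seen = t

    for s in out.values():
        s.active_both_periods = s.morning_departures > 0 and s.afternoon_departures > 0
        s.n_reads_total = read_counts.get(s.tag_id, 0)
        if s.tag_id in read_first:
            s.first_seen = read_first[s.tag_id]
            s.last_seen = read_last[s.tag_id]
    return [out[tag] for tag in sorted(out)]


def period_fractions(summaries: Sequence[DroneSummary], cohort_size: int) -> tuple[float, float]:
    """(morning_fraction, both_fraction) over the tagged cohort.

    The denominator is every tagged drone, including never-detected ones,
    matching how the cohort percentages are reported.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    morning = sum(1 for s in summaries if s.morning_departures > 0)
    both = sum(1 for s in summaries if s.active_both_periods)
    return morning / cohort_size, both / cohort_size


def _completed_outside(spans: Sequence[Span]) -> list[Span]:
    return [s for s in spans if s.location == OUTSIDE and s.censored == "none" and s.duration_s is not None]


def hourly_profile(spans: Sequence[Span]) -> pd.DataFrame:
    """Flight counts by departure hour (rows 0-23) x duration class (columns)."""
    profile = pd.DataFrame(
        0, index=pd.RangeIndex(24, name="hour"), columns=list(DURATION_CLASSES), dtype=int
    )
    for span in _completed_outside(spans):
        profile.loc[span.start.hour, duration_class(span.duration_s)] += 1
    return profile


def duration_class_marginals(profile: pd.DataFrame) -> pd.Series:
    """Share of flights per duration class (sums to 1 when any flights exist)."""
    totals = profile.sum(axis=0)
    grand = totals.sum()
    return totals / grand if grand else totals.astype(float)


def departure_groups(
    departures: Sequence[tuple[str, datetime]] | pd.DataFrame,
    windows: Mapping[str, tuple[float, float]] = DEFAULT_GROUP_WINDOWS,
) -> pd.DataFrame:
    """Assign departures to clock-time groups; out-of-window ones are 'ungrouped'.

    ``departures`` is (tag_id, timestamp) pairs or a frame with those
    columns.  Overlapping windows are a hard error.
    """
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (name_a, (_, end_a)), (name_b, (start_b, _)) in zip(items, items[1:]):
        if end_a > start_b:
            raise ValueError(f"group windows {name_a!r} and {name_b!r} overlap")
    if isinstance(departures, pd.DataFrame):
        pairs = list(zip(departures["tag_id"], pd.to_datetime(departures["timestamp"])))
    else:
        pairs = list(departures)

    rows = []
    for tag, ts in pairs:
        ts = pd.Timestamp(ts).to_pydatetime()
        clock = ts.hour + ts.minute / 60 + ts.second / 3600
        group = "ungrouped"
        for name, (lo, hi) in windows.items():
            if lo <= clock < hi:
                group = name
                break
        rows.append((tag, ts, group))
    return pd.DataFrame(rows, columns=["tag_id", "timestamp", "group"])


def unusual_activity(
    spans: Sequence[Span],
    min_duration_s: float = 3600.0,
    morning_cutoff_hour: int = 12,
    return_window: tuple[float, float] = (14.0, 18.0),
) -> pd.DataFrame:
    """Flag long morning-departure flights that return at afternoon peak.

    A flight is flagged when it lasted more than ``min_duration_s``, left
    before the morning cutoff, and arrived with clock time inside
    ``return_window`` (hours, inclusive).
    """
    rows = []
    lo, hi = return_window
    for span in _completed_outside(spans):
        if span.duration_s <= min_duration_s:
            continue
        if span.start.hour >= morning_cutoff_hour:
            continue
        arr_clock = span.end.hour + span.end.minute / 60 + span.end.second / 3600
        if lo <= arr_clock <= hi:
            rows.append((span.tag_id, span.start, span.end, span.duration_s / 60.0))
    return pd.DataFrame(rows, columns=["tag_id", "departure", "arrival", "duration_min"])


def daily_series(
    spans: Sequence[Span],
    window_start: date | datetime,
    window_end: date | datetime,
) -> pd.DataFrame:
    """Per-date flight counts over [window_start, window_end), zero-filled.

    A flight belongs to the date it departed, even if it returned after
    midnight.  Days without flights report an empty mean duration (NaN).
    """
    start = window_start.date() if isinstance(window_start, datetime) else window_start
    end = window_end.date() if isinstance(window_end, datetime) else window_end
    if end <= start:
        raise ValueError("window_end must be after window_start")
    dates = [start + timedelta(days=k) for k in range((end - start).days)]

    per_day_durations: dict[date, list[float]] = {d: [] for d in dates}
    per_day_tags: dict[date, set[str]] = {d: set() for d in dates}
    for span in _completed_outside(spans):
        day = span.start.date()
        if day in per_day_durations:
            per_day_durations[day].append(span.duration_s / 60.0)
            per_day_tags[day].add(span.tag_id)

    return pd.DataFrame(
        {
            "date": [d.isoformat() for d in dates],
            "n_flights": [len(per_day_durations[d]) for d in dates],
            "n_active_drones": [len(per_day_tags[d]) for d in dates],
            "mean_flight_duration_min": [
                float(np.mean(per_day_durations[d])) if per_day_durations[d] else np.nan for d in dates
            ],
        }
    )


def summaries_frame(summaries: Sequence[DroneSummary]) -> pd.DataFrame:
    """Tabulate drone summaries (category counts expanded to columns)."""
    from dronetrack.behavior import CATEGORIES

    base = pd.DataFrame(
        {
            "tag_id": [s.tag_id for s in summaries],
            "n_flights_completed": [s.n_flights_completed for s in summaries],
            "n_censored_departures": [s.n_censored_departures for s in summaries],
            "n_reads_total": [s.n_reads_total for s in summaries],
            "first_seen": [s.first_seen for s in summaries],
            "last_seen": [s.last_seen for s in summaries],
            "morning_departures": [s.morning_departures for s in summaries],
            "afternoon_departures": [s.afternoon_departures for s in summaries],
            "active_both_periods": [s.active_both_periods for s in summaries],
            "max_inside_days": [s.max_inside_days for s in summaries],
            "max_outside_days": [s.max_outside_days for s in summaries],
        }
    )
    for cat in CATEGORIES:
        base[f"n_{cat}"] = [s.category_counts.get(cat, 0) for s in summaries]
    return base
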