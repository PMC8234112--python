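"""Inside/outside span construction and duration-based behavior labels.

An outside span runs from a departure to the next arrival of the same
tag; an inside span from an arrival to the next departure.  Spans whose
boundary falls outside the recorded window are censored; two same-kind
events in a row bound a 'broken' span (a missed complementary crossing)
that is excluded from duration statistics.

Category edges are lower-exclusive / upper-inclusive:

    outside  d <= 3 min          -> exit_entry (defecation, bearding, feeding)
    outside  3 min < d <= 10 min -> short_mission (orientation flights)
    outside  10 min < d <= 10 h  -> scouting (searching/staying at a DCA)
    outside  d > 10 h            -> extended_absence (days_away attached)
    inside   d <= 30 min         -> brief_inside (re-entry to feed)
    inside   d > 30 min          -> resting (long_stay flag past 10 h)
    right-censored outside       -> departed_drone (last detection)
    broken / left-censored / sub-second -> unresolved
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Literal, Optional, Sequence

import pandas as pd

from dronetrack.detect import ARRIVAL, DEPARTURE, CrossingEvent

OUTSIDE = "outside"
INSIDE = "inside"

CATEGORIES = (
    "exit_entry",
    "short_mission",
    "scouting",
    "resting",
    "brief_inside",
    "extended_absence",
    "departed_drone",
    "unresolved",
)


@dataclass(frozen=True)
class Span:
    """A maximal interval one drone spent outside or inside the hive."""

    tag_id: str
    location: Literal["outside", "inside"]
    start: Optional[datetime]
    end: Optional[datetime]
    duration_s: Optional[float]
    censored: Literal["none", "left", "right", "broken"] = "none"

    @property
    def duration_min(self) -> Optional[float]:
        return None if self.duration_s is None else self.duration_s / 60.0


@dataclass(frozen=True)
class BehaviorLabel:
    category: str
    days_away: Optional[int] = None
    long_stay: bool = False


@dataclass(frozen=True)
class Thresholds:
    """Duration cut points (seconds) for the behavior categories."""

    min_span_s: float = 1.0
    exit_entry_max_s: float = 3 * 60.0
    short_mission_max_s: float = 10 * 60.0
    scouting_max_s: float = 10 * 3600.0
    resting_min_s: float = 30 * 60.0
    day_s: float = 24 * 3600.0

    def __post_init__(self) -> None:
        edges = (self.min_span_s, self.exit_entry_max_s, self.short_mission_max_s, self.scouting_max_s)
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValueError("duration thresholds must be strictly increasing")
        if self.resting_min_s <= 0 or self.day_s <= 0:
            raise ValueError("resting_min_s and day_s must be positive")


DEFAULT_THRESHOLDS = Thresholds()


def build_spans(
    events: Sequence[CrossingEvent],
    window_start: Optional[datetime] = None,
    window_end: Optional[datetime] = None,
) -> list[Span]:
    """Pair consecutive events per tag into inside/outside spans.

    A leading arrival yields a left-censored outside span (the drone was
    already out when recording began); a trailing departure yields a
    right-censored outside span.  Events out of order are a hard error.
    """
    by_tag: dict[str, list[CrossingEvent]] = {}
    for ev in events:
        by_tag.setdefault(ev.tag_id, []).append(ev)

    spans: list[Span] = []
    for tag in sorted(by_tag):
        evs = by_tag[tag]
        times = [e.timestamp for e in evs]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"events for tag {tag!r} are not in chronological order")

        first = evs[0]
        if first.kind == ARRIVAL:
            duration = None if window_start is None else (first.timestamp - window_start).total_seconds()
            spans.append(
                Span(tag, OUTSIDE, window_start, first.timestamp, duration, censored="left")
            )

        for prev, cur in zip(evs, evs[1:]):
            duration = (cur.timestamp - prev.timestamp).total_seconds()
            if prev.kind == DEPARTURE and cur.kind == ARRIVAL:
                spans.append(Span(tag, OUTSIDE, prev.timestamp, cur.timestamp, duration))
            elif prev.kind == ARRIVAL and cur.kind == DEPARTURE:
                spans.append(Span(tag, INSIDE, prev.timestamp, cur.timestamp, duration))
            elif prev.kind == DEPARTURE:  # departure, departure: lost arrival
                spans.append(Span(tag, OUTSIDE, prev.timestamp, cur.timestamp, duration, censored="broken"))
            else:  # arrival, arrival: lost departure
                spans.append(Span(tag, INSIDE, prev.timestamp, cur.timestamp, duration, censored="broken"))

        last = evs[-1]
        if last.kind == DEPARTURE:
            duration = None if window_end is None else (window_end - last.timestamp).total_seconds()
            spans.append(Span(tag, OUTSIDE, last.timestamp, window_end, duration, censored="right"))

    return spans


def classify_span(span: Span, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> BehaviorLabel:
    """Map one span to its behavior category.

    Classification depends only on location, duration and censoring, so
    it is idempotent and order-independent by construction.
    """
    if span.censored == "right" and span.location == OUTSIDE:
        return BehaviorLabel("departed_drone")
    if span.censored in ("broken", "left"):
        return BehaviorLabel("unresolved")
    if span.duration_s is None:
        return BehaviorLabel("unresolved")
    if span.duration_s < 0:
        raise ValueError(f"negative span duration: {span.duration_s}")
    d = span.duration_s
    if d < thresholds.min_span_s:
        return BehaviorLabel("unresolved")

    if span.location == OUTSIDE:
        if d <= thresholds.exit_entry_max_s:
            return BehaviorLabel("exit_entry")
        if d <= thresholds.short_mission_max_s:
            return BehaviorLabel("short_mission")
        if d <= thresholds.scouting_max_s:
            return BehaviorLabel("scouting")
        days_away = int(d // thresholds.day_s) + 1
        return BehaviorLabel("extended_absence", days_away=days_away)

    # inside
    if d > thresholds.resting_min_s:
        return BehaviorLabel("resting", long_stay=d > thresholds.scouting_max_s)
    return BehaviorLabel("brief_inside")


def classify_spans(
    spans: Sequence[Span], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[BehaviorLabel]:
    return [classify_span(s, thresholds) for s in spans]


def spans_frame(spans: Sequence[Span], labels: Optional[Sequence[BehaviorLabel]] = None) -> pd.DataFrame:
    """Tabulate spans (and optional labels) for CSV output."""
    frame = pd.DataFrame(
        {
            "tag_id": [s.tag_id for s in spans],
            "location": [s.location for s in spans],
            "start": [s.start for s in spans],
            "end": [s.end for s in spans],
            "duration_s": [s.duration_s for s in spans],
            "censored": [s.censored for s in spans],
        }
    )
    if labels is not None:
        frame["category"] = [lb.category for lb in labels]
        frame["days_away"] = [lb.days_away for lb in labels]
        frame["long_stay"] = [lb.long_stay for lb in labels]
    return frame
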