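"""Agent-based generator of drone entrance traffic and noisy RFID reads.

Each tagged drone is simulated through the observation window as an
agent that schedules flights day by day, draws a flight-duration class
from a configurable mix, and emits the sensor-read triples a two-sensor
entrance reader would record (A,B,B on the way out; B,A,A on the way
in).  Every true crossing is also emitted as a ground-truth event, so
downstream detection and classification can be validated exactly.

Channel noise is opt-in: per-read dropout (``p_read``), spurious
duplicate reads (``p_spurious``), drones whose tag never responds
(``p_never_detected``) and drones whose whole record is one stray read
(``p_single_read``).  The last two groups carry no ground-truth events:
their flights were never observable.

Departure clock times follow a four-component truncated-normal mixture
(03:00, 06:00, noon, and a dominant afternoon peak), so a configurable
minority of drones is active at dawn and in the morning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from dronetrack.rfid_io import TagRead

BEHAVIOR_CLASSES = ("under_3min", "3_to_10min", "10_to_60min", "over_60min")

#: sampling ranges (seconds) per class, kept clear of the 3 min / 10 min /
#: 10 h classification edges so boundary ambiguity cannot arise by chance
_CLASS_DURATION_S = {
    "under_3min": (20.0, 170.0),
    "3_to_10min": (195.0, 590.0),
    "10_to_60min": (630.0, 3500.0),
    "over_60min": (3900.0, 30000.0),
}

_PROB_FIELDS = (
    "p_never_detected",
    "p_single_read",
    "p_permanent_departure",
    "p_drift",
    "p_long_rest",
    "p_read",
    "p_spurious",
    "p_day_active",
    "morning_active_fraction",
    "both_period_fraction",
)


@dataclass
class SimConfig:
    """Parameters of one simulated monitoring run (defaults: 200 drones, 45 days)."""

    n_drones: int = 200
    start_date: date = date(2017, 10, 15)
    end_date: date = date(2017, 11, 29)
    p_never_detected: float = 0.08
    p_single_read: float = 0.10
    behavior_mix: dict[str, float] = field(
        default_factory=lambda: {
            "under_3min": 0.073,
            "3_to_10min": 0.7622,
            "10_to_60min": 0.124,
            "over_60min": 0.04,
        }
    )
    afternoon_peak_hour: float = 15.0
    morning_active_fraction: float = 0.215
    both_period_fraction: float = 0.16
    p_permanent_departure: float = 0.01
    p_drift: float = 0.01
    p_long_rest: float = 0.02
    p_read: float = 1.0
    p_spurious: float = 0.0
    zero_activity_dates: tuple[date, ...] = ()
    p_day_active: float = 0.55
    flights_per_day_lambda: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_drones < 1:
            raise ValueError("n_drones must be >= 1")
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        for name in _PROB_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if set(self.behavior_mix) != set(BEHAVIOR_CLASSES):
            raise ValueError(f"behavior_mix must have exactly the keys {BEHAVIOR_CLASSES}")
        if any(p < 0 for p in self.behavior_mix.values()):
            raise ValueError("behavior_mix probabilities must be >= 0")
        total = sum(self.behavior_mix.values())
        if abs(total - 1.0) > 2e-2:
            raise ValueError(f"behavior_mix must sum to 1, got {total}")
        if abs(total - 1.0) > 1e-9:  # renormalize printed percentages (e.g. 99.92%)
            self.behavior_mix = {k: v / total for k, v in self.behavior_mix.items()}
        p_active = 1.0 - self.p_never_detected - self.p_single_read
        if p_active < 0:
            raise ValueError("p_never_detected + p_single_read must be <= 1")
        if self.morning_active_fraction > p_active:
            raise ValueError("morning_active_fraction cannot exceed the active-drone fraction")
        if self.both_period_fraction > self.morning_active_fraction:
            raise ValueError("both_period_fraction cannot exceed morning_active_fraction")
        self.zero_activity_dates = tuple(self.zero_activity_dates)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days

    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=k) for k in range(self.n_days)]

    def window(self) -> tuple[datetime, datetime]:
        return (
            datetime.combine(self.start_date, time.min),
            datetime.combine(self.end_date, time.min),
        )


@dataclass(frozen=True)
class GroundTruthEvent:
    """One true hive crossing, with the duration class sampled for its flight."""

    tag_id: str
    kind: Literal["departure", "arrival"]
    true_time: datetime
    behavior_class: str


@dataclass(frozen=True)
class WeatherDay:
    date: date
    mean_temp: float
    precipitation: float


# clock-time mixture components: (center hour, sd hours, weight)
_MORNING_COMPONENTS = ((3.0, 0.8, 0.30), (6.0, 1.0, 0.45), (12.0, 1.0, 0.25))
_MORNING_RANGE = (0.5, 11.98)
_AFTERNOON_RANGE = (12.0, 21.5)


def _draw_clock_hour(
    rng: np.random.Generator,
    components: Sequence[tuple[float, float, float]],
    lo: float,
    hi: float,
) -> float:
    weights = np.array([w for _, _, w in components])
    weights = weights / weights.sum()
    k = rng.choice(len(components), p=weights)
    center, sd, _ = components[k]
    for _ in range(200):  # truncation by rejection
        h = rng.normal(center, sd)
        if lo <= h < hi:
            return h
    return float(np.clip(rng.uniform(lo, hi), lo, hi))


def _sample_duration_s(rng: np.random.Generator, cls: str) -> float:
    lo, hi = _CLASS_DURATION_S[cls]
    return float(rng.uniform(lo, hi))


def _traffic_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _weather_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def tag_ids(config: SimConfig) -> list[str]:
    """Roster of tagged-drone identifiers for a run."""
    width = max(3, len(str(config.n_drones)))
    return [f"D{i:0{width}d}" for i in range(1, config.n_drones + 1)]


def _emit_triple(
    rng: np.random.Generator,
    reads: list[TagRead],
    tag: str,
    kind: str,
    when: datetime,
    p_read: float,
    p_spurious: float,
) -> None:
    sensors = ("A", "B", "B") if kind == "departure" else ("B", "A", "A")
    g1 = int(rng.integers(1, 4))
    g2 = int(rng.integers(1, 4))
    times = (when - timedelta(seconds=g1), when, when + timedelta(seconds=g2))
    for sensor, ts in zip(sensors, times):
        if rng.random() < p_read:
            reads.append(TagRead(tag, ts, sensor))
            if p_spurious > 0 and rng.random() < p_spurious:
                offset = int(rng.integers(1, 3))
                reads.append(TagRead(tag, ts + timedelta(seconds=offset), sensor))


def simulate_traffic(config: SimConfig) -> tuple[list[TagRead], list[GroundTruthEvent]]:
    """Simulate the full run; returns the noisy read stream and ground truth.

    Reads are returned chronologically (the reader's own order); ground
    truth is sorted by (tag, time) and strictly alternates
    departure/arrival per tag, with a final unpaired departure exactly
    when the drone never returned.  No true departure falls on a
    ``zero_activity_date``.  Output is reproducible for a fixed seed.
    """
    config.validate()
    rng = _traffic_rng(config)

    p_active = 1.0 - config.p_never_detected - config.p_single_read
    p_morning_given_active = config.morning_active_fraction / p_active if p_active > 0 else 0.0
    p_both_given_morning = (
        config.both_period_fraction / config.morning_active_fraction
        if config.morning_active_fraction > 0
        else 0.0
    )
    mix_probs = np.array([config.behavior_mix[c] for c in BEHAVIOR_CLASSES])
    allowed_dates = [d for d in config.dates() if d not in set(config.zero_activity_dates)]
    window_start, _ = config.window()

    reads: list[TagRead] = []
    truth: list[GroundTruthEvent] = []

    for tag in tag_ids(config):
        u = rng.random()
        morning_flag = rng.random() < p_morning_given_active
        both_flag = morning_flag and rng.random() < p_both_given_morning

        if u < config.p_never_detected:
            continue
        if u < config.p_never_detected + config.p_single_read:
            day = allowed_dates[int(rng.integers(0, len(allowed_dates)))] if allowed_dates else config.start_date
            second = int(rng.integers(0, 86400))
            sensor = "A" if rng.random() < 0.5 else "B"
            reads.append(TagRead(tag, datetime.combine(day, time.min) + timedelta(seconds=second), sensor))
            continue

        if not allowed_dates:
            continue
        active_days = [d for d in allowed_dates if rng.random() < config.p_day_active]
        if not active_days:
            active_days = [allowed_dates[0]]

        busy_until = window_start - timedelta(days=1)
        gone = False
        afternoon_components = (
            (12.0, 1.0, 0.25),
            (config.afternoon_peak_hour, 1.8, 0.75),
        )
        for day_idx, day in enumerate(active_days):
            if gone:
                break
            n_flights = 1 + int(rng.poisson(config.flights_per_day_lambda))
            hours: list[float] = []
            for _ in range(n_flights):
                if morning_flag and not both_flag:
                    hours.append(_draw_clock_hour(rng, _MORNING_COMPONENTS, *_MORNING_RANGE))
                elif both_flag:
                    if rng.random() < 0.4:
                        hours.append(_draw_clock_hour(rng, _MORNING_COMPONENTS, *_MORNING_RANGE))
                    else:
                        hours.append(_draw_clock_hour(rng, afternoon_components, *_AFTERNOON_RANGE))
                else:
                    hours.append(_draw_clock_hour(rng, afternoon_components, *_AFTERNOON_RANGE))
            if day_idx == 0:
                # the period flags are promises: guarantee them on the first active day
                if morning_flag and not any(h < 12.0 for h in hours):
                    hours.append(_draw_clock_hour(rng, _MORNING_COMPONENTS, *_MORNING_RANGE))
                if both_flag and not any(h >= 12.0 for h in hours):
                    hours.append(_draw_clock_hour(rng, afternoon_components, *_AFTERNOON_RANGE))

            for h in sorted(hours):
                dep_dt = datetime.combine(day, time.min) + timedelta(seconds=int(round(h * 3600)))
                if dep_dt <= busy_until:
                    continue
                cls = BEHAVIOR_CLASSES[int(rng.choice(len(BEHAVIOR_CLASSES), p=mix_probs))]
                duration_s = _sample_duration_s(rng, cls)
                if cls == "over_60min" and rng.random() < config.p_drift:
                    duration_s = float(rng.uniform(1.0, 3.0)) * 86400.0  # drifting absence
                arr_dt = dep_dt + timedelta(seconds=int(round(duration_s)))

                truth.append(GroundTruthEvent(tag, "departure", dep_dt, cls))
                _emit_triple(rng, reads, tag, "departure", dep_dt, config.p_read, config.p_spurious)

                if cls in ("10_to_60min", "over_60min") and rng.random() < config.p_permanent_departure:
                    gone = True  # left for a DCA and never came back
                    break

                truth.append(GroundTruthEvent(tag, "arrival", arr_dt, cls))
                _emit_triple(rng, reads, tag, "arrival", arr_dt, config.p_read, config.p_spurious)

                inside_gap_s = math.exp(rng.normal(math.log(1200.0), 1.0))
                if rng.random() < config.p_long_rest:
                    inside_gap_s = float(rng.uniform(1.0, 4.0)) * 86400.0
                busy_until = arr_dt + timedelta(seconds=max(60.0, inside_gap_s))

    reads.sort(key=lambda r: (r.timestamp, r.tag_id, r.sensor))
    truth.sort(key=lambda e: (e.tag_id, e.true_time))
    return reads, truth


def simulate_weather(config: SimConfig) -> list[WeatherDay]:
    """One weather row per date; zero-activity dates get extreme heat or rain."""
    config.validate()
    rng = _weather_rng(config)
    shutdown = set(config.zero_activity_dates)
    out: list[WeatherDay] = []
    for day in config.dates():
        if day in shutdown:
            if rng.random() < 0.5:
                temp = float(rng.uniform(38.0, 42.0))  # heat shutdown
                precip = 0.0
            else:
                temp = float(rng.normal(29.0, 2.0))
                precip = float(rng.uniform(14.0, 30.0))  # heavy-rain shutdown
        else:
            temp = float(np.clip(rng.normal(27.0, 3.0), 16.0, 36.0))
            precip = 0.0 if rng.random() < 0.7 else float(rng.uniform(0.1, 10.0))
        out.append(WeatherDay(day, round(temp, 2), round(precip, 2)))
    return out


def truth_frame(truth: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [e.tag_id for e in truth],
            "kind": [e.kind for e in truth],
            "timestamp": [e.true_time for e in truth],
            "behavior_class": [e.behavior_class for e in truth],
        }
    )


def weather_frame(weather: Sequence[WeatherDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [w.date.isoformat() for w in weather],
            "mean_temp": [w.mean_temp for w in weather],
            "precipitation": [w.precipitation for w in weather],
        }
    )


def completed_flights(truth: Sequence[GroundTruthEvent]) -> list[tuple[str, datetime, datetime, str]]:
    """Pair ground-truth events into completed (tag, depart, arrive, class) flights."""
    flights = []
    by_tag: dict[str, list[GroundTruthEvent]] = {}
    for ev in truth:
        by_tag.setdefault(ev.tag_id, []).append(ev)
    for tag, events in by_tag.items():
        for prev, cur in zip(events, events[1:]):
            if prev.kind == "departure" and cur.kind == "arrival":
                flights.append((tag, prev.true_time, cur.true_time, prev.behavior_class))
    return flights


def n_flights_by_tag(truth: Sequence[GroundTruthEvent]) -> dict[str, int]:
    """Completed flights per tag in the ground truth."""
    counts: dict[str, int] = {}
    for tag, *_ in completed_flights(truth):
        counts[tag] = counts.get(tag, 0) + 1
    return counts


__all__ = [
    "SimConfig",
    "GroundTruthEvent",
    "WeatherDay",
    "BEHAVIOR_CLASSES",
    "simulate_traffic",
    "simulate_weather",
    "tag_ids",
    "truth_frame",
    "weather_frame",
    "completed_flights",
    "n_flights_by_tag",
]
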