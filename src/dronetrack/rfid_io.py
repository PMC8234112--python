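"""Delimited-text I/O for RFID read logs and pipeline record types.

All files are plain CSV.  Timestamps are serialized as ISO 8601 local
civil time with second resolution and no timezone offset; the reader
hardware reports clock time and the analysis never crosses timezones.

The reader validates sensor labels hard (an unknown sensor is a data
corruption, not noise) but tolerates unparseable timestamps by tallying
and dropping the affected lines, so one bad row cannot sink a
multi-week log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"

VALID_SENSORS = frozenset({"A", "B"})


@dataclass(frozen=True, order=True)
class TagRead:
    """One raw RFID detection: a tag seen at one sensor at one instant."""

    tag_id: str
    timestamp: datetime
    sensor: str

    def __post_init__(self) -> None:
        if self.sensor not in VALID_SENSORS:
            raise ValueError(f"unknown sensor label {self.sensor!r}; expected one of A, B")


@dataclass(frozen=True)
class Dialect:
    """Column naming and timestamp layout of a raw reader log."""

    tag_col: str = "tag_id"
    time_col: str = "timestamp"
    sensor_col: str = "sensor"
    time_format: str = TIME_FORMAT


@dataclass
class ReadReport:
    """Tally of lines accepted/rejected while parsing one log file."""

    n_lines: int = 0
    n_accepted: int = 0
    n_rejected_timestamp: int = 0
    rejected_line_numbers: list[int] = field(default_factory=list)


def read_log(path: str | Path, dialect: Dialect = Dialect()) -> tuple[list[TagRead], ReadReport]:
    """Parse a raw reader log into sorted :class:`TagRead` records.

    Returns reads sorted by ``(tag_id, timestamp, input order)`` together
    with a :class:`ReadReport`.  A missing column raises ``ValueError``
    naming the column; a sensor label outside {A, B} raises ``ValueError``;
    lines with unparseable timestamps are rejected and tallied.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], ReadReport()
    for col in (dialect.tag_col, dialect.time_col, dialect.sensor_col):
        if col not in frame.columns:
            raise ValueError(f"input log {path} is missing required column {col!r}")

    report = ReadReport(n_lines=len(frame))
    if frame.empty:
        return [], report

    sensors = frame[dialect.sensor_col].str.strip()
    bad_sensor = ~sensors.isin(VALID_SENSORS)
    if bad_sensor.any():
        value = sensors[bad_sensor].iloc[0]
        raise ValueError(f"unknown sensor label {value!r} in {path}; expected one of A, B")

    times = pd.to_datetime(frame[dialect.time_col], format=dialect.time_format, errors="coerce")
    bad_time = times.isna()
    if bad_time.any():
        report.n_rejected_timestamp = int(bad_time.sum())
        report.rejected_line_numbers = [int(i) + 2 for i in frame.index[bad_time]]  # 1-based + header
        log.warning(
            "%s: rejected %d line(s) with unparseable timestamps (lines %s)",
            path,
            report.n_rejected_timestamp,
            report.rejected_line_numbers,
        )

    keep = ~bad_time
    reads = [
        TagRead(tag_id=t, timestamp=ts.to_pydatetime(), sensor=s)
        for t, ts, s in zip(frame[dialect.tag_col][keep], times[keep], sensors[keep])
    ]
    report.n_accepted = len(reads)
    order = sorted(range(len(reads)), key=lambda i: (reads[i].tag_id, reads[i].timestamp, i))
    return [reads[i] for i in order], report


def write_reads(path: str | Path, reads: Iterable[TagRead], dialect: Dialect = Dialect()) -> None:
    """Write reads as CSV in the given dialect (chronological order kept)."""
    frame = pd.DataFrame(
        {
            dialect.tag_col: [r.tag_id for r in reads],
            dialect.time_col: [r.timestamp.strftime(dialect.time_format) for r in reads],
            dialect.sensor_col: [r.sensor for r in reads],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generic record-frame round-tripping
#
# Events, spans, labels and summaries are moved around as pandas frames with
# a declared set of datetime columns so that CSV round-trips are lossless.
# ---------------------------------------------------------------------------

EVENT_TIME_COLS = ("timestamp",)
SPAN_TIME_COLS = ("start", "end")


def write_frame(path: str | Path, frame: pd.DataFrame, time_cols: Sequence[str] = ()) -> None:
    out = frame.copy()
    for col in time_cols:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime(TIME_FORMAT)
    out.to_csv(path, index=False)


def read_frame(path: str | Path, time_cols: Sequence[str] = ()) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in time_cols:
        if col in frame.columns:
            frame[col] = pd.to_datetime(frame[col], format=TIME_FORMAT)
    return frame


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    """Write a crossing-event table (see :func:`dronetrack.detect.events_frame`)."""
    write_frame(path, events, EVENT_TIME_COLS)


def read_events(path: str | Path) -> pd.DataFrame:
    return read_frame(path, EVENT_TIME_COLS)


def write_spans(path: str | Path, spans: pd.DataFrame) -> None:
    """Write a span table (see :func:`dronetrack.behavior.spans_frame`)."""
    write_frame(path, spans, SPAN_TIME_COLS)


def read_spans(path: str | Path) -> pd.DataFrame:
    return read_frame(path, SPAN_TIME_COLS)


def write_summary(path: str | Path, summary: pd.DataFrame) -> None:
    write_frame(path, summary, ("first_seen", "last_seen"))


def read_summary(path: str | Path) -> pd.DataFrame:
    return read_frame(path, ("first_seen", "last_seen"))
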