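"""Configurable simulate -> detect -> classify -> summarize -> compare pipeline.

Every stage is a pure function of (inputs, config, seed); a fixed seed
gives byte-identical artifacts.  The run log records a hash of the
resolved configuration and record counts at each stage, so two runs can
be compared without diffing every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Any, Optional

from dronetrack import behavior, detect, rfid_io, stats, summary, synthetic

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class DetectionConfig:
    mode: str = "strict"
    debounce_s: float = 0.0


@dataclass
class SummaryConfig:
    morning_cutoff_hour: int = 12
    group_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(summary.DEFAULT_GROUP_WINDOWS)
    )


@dataclass
class StatsConfig:
    flight_count_bin_edges: tuple[float, ...] = (1, 10, 30, 50)


@dataclass
class PipelineConfig:
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    thresholds: behavior.Thresholds = field(default_factory=behavior.Thresholds)
    summary: SummaryConfig = field(default_factory=SummaryConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> None:
        self.sim.validate()
        if self.detection.mode not in ("strict", "lenient"):
            raise ValueError(f"unknown detection mode {self.detection.mode!r}")
        if self.detection.debounce_s < 0:
            raise ValueError("debounce_s must be >= 0")
        if not 0 <= self.summary.morning_cutoff_hour <= 24:
            raise ValueError("morning_cutoff_hour must be a valid clock hour")


def _coerce_dates(section: dict[str, Any]) -> dict[str, Any]:
    out = dict(section)
    for key in ("start_date", "end_date"):
        if key in out and isinstance(out[key], str):
            out[key] = date.fromisoformat(out[key])
    if "zero_activity_dates" in out:
        out["zero_activity_dates"] = tuple(
            date.fromisoformat(d) if isinstance(d, str) else d for d in out["zero_activity_dates"]
        )
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config with optional [simulate]/[detect]/[classify]/[summarize]/[stats] sections."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig(
        sim=synthetic.SimConfig(**_coerce_dates(raw.get("simulate", {}))),
        detection=DetectionConfig(**raw.get("detect", {})),
        thresholds=behavior.Thresholds(**raw.get("classify", {})),
    )
    summarize = raw.get("summarize", {})
    if "morning_cutoff_hour" in summarize:
        cfg.summary.morning_cutoff_hour = int(summarize["morning_cutoff_hour"])
    if "group_windows" in summarize:
        cfg.summary.group_windows = {
            name: (float(lo), float(hi)) for name, (lo, hi) in summarize["group_windows"].items()
        }
    if "flight_count_bin_edges" in raw.get("stats", {}):
        cfg.stats.flight_count_bin_edges = tuple(raw["stats"]["flight_count_bin_edges"])
    cfg.validate()
    return cfg


def config_hash(config: PipelineConfig) -> str:
    def default(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (date, datetime)):
            return obj.isoformat()
        return str(obj)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(config: PipelineConfig, out: Path) -> dict[str, Any]:
    reads, truth = synthetic.simulate_traffic(config.sim)
    weather = synthetic.simulate_weather(config.sim)
    rfid_io.write_reads(out / "reads.csv", reads)
    rfid_io.write_frame(out / "truth.csv", synthetic.truth_frame(truth), ("timestamp",))
    synthetic.weather_frame(weather).to_csv(out / "weather.csv", index=False)
    return {"n_reads": len(reads), "n_truth_events": len(truth), "n_weather_days": len(weather)}


@_stage("detect")
def _run_detect(config: PipelineConfig, out: Path, reads) -> tuple[list, dict[str, Any]]:
    events, report = detect.detect_events(
        reads, mode=config.detection.mode, debounce_s=config.detection.debounce_s
    )
    rfid_io.write_events(out / "events.csv", detect.events_frame(events))
    return events, {
        "n_events": len(events),
        "n_reads_consumed": report.n_reads_consumed,
        "n_reads_unmatched": report.n_reads_unmatched,
        "n_inconsistent_transitions": report.n_inconsistent_transitions,
    }


@_stage("classify")
def _run_classify(config: PipelineConfig, out: Path, events) -> tuple[list, list, dict[str, Any]]:
    window_start, window_end = config.sim.window()
    spans = behavior.build_spans(events, window_start, window_end)
    labels = behavior.classify_spans(spans, config.thresholds)
    rfid_io.write_spans(out / "spans.csv", behavior.spans_frame(spans, labels))
    return spans, labels, {"n_spans": len(spans)}


@_stage("summarize")
def _run_summarize(config: PipelineConfig, out: Path, spans, labels, reads, events) -> dict[str, Any]:
    roster = synthetic.tag_ids(config.sim)
    cohort = summary.cohort_report(reads, roster)
    summaries = summary.summarize_drones(
        spans, labels, reads=reads, morning_cutoff_hour=config.summary.morning_cutoff_hour
    )
    rfid_io.write_summary(out / "summaries.csv", summary.summaries_frame(summaries))

    profile = summary.hourly_profile(spans)
    profile.reset_index().to_csv(out / "hourly_profile.csv", index=False)

    window_start, window_end = config.sim.window()
    daily = summary.daily_series(spans, window_start, window_end)
    daily.to_csv(out / "daily.csv", index=False)

    departures = [(e.tag_id, e.timestamp) for e in events if e.kind == detect.DEPARTURE]
    groups = summary.departure_groups(departures, config.summary.group_windows)
    rfid_io.write_frame(out / "departure_groups.csv", groups, ("timestamp",))

    unusual = summary.unusual_activity(spans, morning_cutoff_hour=config.summary.morning_cutoff_hour)
    rfid_io.write_frame(out / "unusual_activity.csv", unusual, ("departure", "arrival"))

    morning_fraction, both_fraction = summary.period_fractions(summaries, len(roster))
    return {
        "n_drones_summarized": len(summaries),
        "cohort": {
            "n_tagged": cohort.n_tagged,
            "n_never_detected": cohort.n_never_detected,
            "pct_never_detected": cohort.pct_never_detected,
            "n_single_read": cohort.n_single_read,
            "pct_single_read": cohort.pct_single_read,
        },
        "morning_fraction": morning_fraction,
        "both_fraction": both_fraction,
        "n_flights_total": int(sum(s.n_flights_completed for s in summaries)),
    }


@_stage("compare")
def _run_compare(config: PipelineConfig, out: Path, spans, labels) -> dict[str, Any]:
    summaries = summary.summarize_drones(spans, labels)
    counts = [s.n_flights_completed for s in summaries]
    gof = stats.flight_count_gof(counts, config.stats.flight_count_bin_edges)

    window_start, window_end = config.sim.window()
    daily = summary.daily_series(spans, window_start, window_end)
    weather = synthetic.weather_frame(synthetic.simulate_weather(config.sim))
    corr = stats.weather_correlation(daily, weather)

    def res(t: stats.TestResult) -> dict[str, Any]:
        return {"statistic": t.statistic, "p_value": t.p_value, "df": t.df, "method": t.method}

    results = {
        "flight_count_chi2": res(gof),
        "r_temp": res(corr.r_temp),
        "r_precip": res(corr.r_precip),
        "r_temp_precip": res(corr.r_temp_precip),
    }
    (out / "stats.json").write_text(json.dumps(results, indent=2, allow_nan=True))
    return {"flight_count_chi2": gof.statistic, "df": gof.df}


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    out_dir: str | Path = "dronetrack_run",
    seed: Optional[int] = None,
) -> Path:
    """Run every stage end to end; returns the artifact directory."""
    config = config or PipelineConfig()
    if seed is not None:
        config.sim.seed = seed
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    run_log: dict[str, Any] = {"config_hash": config_hash(config), "seed": config.sim.seed, "stages": {}}

    run_log["stages"]["simulate"] = _run_simulate(config, out)
    reads, _ = rfid_io.read_log(out / "reads.csv")
    events, detect_counts = _run_detect(config, out, reads)
    run_log["stages"]["detect"] = detect_counts
    spans, labels, classify_counts = _run_classify(config, out, events)
    run_log["stages"]["classify"] = classify_counts
    run_log["stages"]["summarize"] = _run_summarize(config, out, spans, labels, reads, events)
    run_log["stages"]["compare"] = _run_compare(config, out, spans, labels)

    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return out
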