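"""Activity aggregation tests: cohort report, profiles, daily series, groups."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from dronetrack.behavior import build_spans, classify_spans
from dronetrack.detect import CrossingEvent, detect_events
from dronetrack.rfid_io import TagRead
from dronetrack.summary import (
    cohort_report,
    daily_series,
    departure_groups,
    duration_class,
    duration_class_marginals,
    hourly_profile,
    period_fractions,
    summarize_drones,
    summaries_frame,
    unusual_activity,
)
from dronetrack.synthetic import SimConfig, n_flights_by_tag, simulate_traffic, tag_ids

W0 = datetime(2017, 10, 15)
W1 = datetime(2017, 10, 25)


def flight(tag, dep, duration_min):
    dep_dt = W0.replace(hour=0) + dep if isinstance(dep, timedelta) else dep
    return [
        CrossingEvent(tag, "departure", dep_dt),
        CrossingEvent(tag, "arrival", dep_dt + timedelta(minutes=duration_min)),
    ]


def spans_for(events):
    spans = build_spans(events, W0, W1)
    return spans, classify_spans(spans)


def at(day, hour, minute=0):
    return datetime(2017, 10, day, hour, minute)


class TestSummarizeDrones:
    def test_three_completed_flights(self):
        events = flight("T1", at(16, 14), 7) + flight("T1", at(17, 15), 5) + flight("T1", at(18, 15), 20)
        spans, labels = spans_for(events)
        (s,) = summarize_drones(spans, labels)
        assert s.n_flights_completed == 3
        assert s.n_censored_departures == 0

    def test_censored_final_departure_counted_separately(self):
        events = flight("T1", at(16, 14), 7) + [CrossingEvent("T1", "departure", at(17, 15))]
        spans, labels = spans_for(events)
        (s,) = summarize_drones(spans, labels)
        assert s.n_flights_completed == 1
        assert s.n_censored_departures == 1

    def test_morning_plus_afternoon_equals_total_departures(self):
        events = flight("T1", at(16, 9), 7) + flight("T1", at(16, 15), 7) + [
            CrossingEvent("T1", "departure", at(17, 16))
        ]
        spans, labels = spans_for(events)
        (s,) = summarize_drones(spans, labels)
        assert s.morning_departures == 1
        assert s.afternoon_departures == 2
        assert s.morning_departures + s.afternoon_departures == 3
        assert s.active_both_periods

    def test_permutation_invariance(self):
        events = flight("T1", at(16, 14), 7) + flight("T2", at(16, 9), 5)
        spans, labels = spans_for(events)
        rev = summarize_drones(list(reversed(spans)), list(reversed(labels)))
        fwd = summarize_drones(spans, labels)
        assert summaries_frame(fwd).equals(summaries_frame(rev))

    def test_max_outside_days(self):
        events = flight("T1", at(16, 9), 26 * 60)  # 26 h away
        spans, labels = spans_for(events)
        (s,) = summarize_drones(spans, labels)
        assert s.max_outside_days == 2

    def test_noiseless_flight_counts_match_ground_truth(self, small_config):
        reads, truth = simulate_traffic(small_config)
        events, _ = detect_events(reads)
        spans = build_spans(events, *small_config.window())
        labels = classify_spans(spans)
        summaries = summarize_drones(spans, labels, reads=reads)
        truth_counts = n_flights_by_tag(truth)
        for s in summaries:
            assert s.n_flights_completed == truth_counts.get(s.tag_id, 0)


class TestCohortReport:
    def test_printed_cohort_percentages(self):
        roster = [f"D{i:03d}" for i in range(1, 201)]
        reads = []
        t0 = at(16, 12)
        for tag in roster[16:36]:  # 20 single-read drones
            reads.append(TagRead(tag, t0, "A"))
        for tag in roster[36:]:  # the rest get full activity
            reads.extend(TagRead(tag, t0 + timedelta(seconds=i), s) for i, s in enumerate("ABB"))
        report = cohort_report(reads, roster)
        assert report.n_never_detected == 16
        assert report.pct_never_detected == 8.0
        assert report.n_single_read == 20
        assert report.pct_single_read == 10.0

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            cohort_report([], [])


class TestPeriodFractions:
    def test_no_morning_activity(self):
        events = flight("T1", at(16, 15), 7)
        spans, labels = spans_for(events)
        assert period_fractions(summarize_drones(spans, labels), 10) == (0.0, 0.0)

    def test_everybody_both_periods(self):
        events = []
        for tag in ("T1", "T2"):
            events += flight(tag, at(16, 10), 5) + flight(tag, at(16, 15), 5)
        spans, labels = spans_for(events)
        assert period_fractions(summarize_drones(spans, labels), 2) == (1.0, 1.0)

    def test_both_never_exceeds_morning(self, small_config):
        reads, _ = simulate_traffic(small_config)
        events, _ = detect_events(reads)
        spans = build_spans(events, *small_config.window())
        summaries = summarize_drones(spans, classify_spans(spans))
        morning, both = period_fractions(summaries, small_config.n_drones)
        assert both <= morning

    def test_zero_cohort_hard_error(self):
        with pytest.raises(ValueError):
            period_fractions([], 0)


class TestHourlyProfile:
    def test_single_flight_lands_in_cell(self):
        events = flight("T1", at(16, 15, 5), 7)
        spans, _ = spans_for(events)
        profile = hourly_profile(spans)
        assert profile.loc[15, "3_to_10min"] == 1
        assert profile.to_numpy().sum() == 1

    def test_marginals_sum_to_one(self):
        events = flight("T1", at(16, 15), 7) + flight("T1", at(17, 6), 2) + flight("T1", at(18, 14), 45)
        spans, _ = spans_for(events)
        marginals = duration_class_marginals(hourly_profile(spans))
        assert marginals.sum() == pytest.approx(1.0)

    def test_grand_total_equals_completed_flights(self, small_config):
        reads, truth = simulate_traffic(small_config)
        events, _ = detect_events(reads)
        spans = build_spans(events, *small_config.window())
        summaries = summarize_drones(spans, classify_spans(spans))
        total = sum(s.n_flights_completed for s in summaries)
        assert hourly_profile(spans).to_numpy().sum() == total

    @pytest.mark.parametrize(
        "seconds,expected",
        [(100, "under_3min"), (180, "under_3min"), (400, "3_to_10min"), (600, "3_to_10min"),
         (2000, "10_to_60min"), (3600, "10_to_60min"), (3601, "over_60min")],
    )
    def test_duration_class_edges(self, seconds, expected):
        assert duration_class(seconds) == expected


class TestDepartureGroups:
    def test_dawn_group(self):
        frame = departure_groups([("T1", at(16, 3, 10))])
        assert list(frame["group"]) == ["dawn"]

    def test_out_of_window_ungrouped(self):
        frame = departure_groups([("T1", at(16, 9, 0))])
        assert list(frame["group"]) == ["ungrouped"]

    def test_late_afternoon_group(self):
        frame = departure_groups([("T1", at(16, 17, 0))])
        assert list(frame["group"]) == ["late_afternoon"]

    def test_overlapping_windows_hard_error(self):
        with pytest.raises(ValueError, match="overlap"):
            departure_groups([("T1", at(16, 3))], {"a": (2.0, 5.0), "b": (4.0, 6.0)})


class TestUnusualActivity:
    def test_long_morning_flight_returning_at_peak_flagged(self):
        events = flight("T1", at(16, 6, 30), 510)  # departs 06:30, arrives 15:00
        spans, _ = spans_for(events)
        flagged = unusual_activity(spans)
        assert len(flagged) == 1
        assert flagged.iloc[0]["tag_id"] == "T1"

    def test_short_morning_flight_not_flagged(self):
        events = flight("T1", at(16, 6, 30), 30)
        spans, _ = spans_for(events)
        assert unusual_activity(spans).empty

    def test_afternoon_departure_not_flagged(self):
        events = flight("T1", at(16, 13, 0), 120)
        spans, _ = spans_for(events)
        assert unusual_activity(spans).empty


class TestDailySeries:
    def test_zero_filled_window(self):
        events = flight("T1", at(16, 15), 4) + flight("T1", at(16, 16), 6)
        spans, _ = spans_for(events)
        daily = daily_series(spans, date(2017, 10, 15), date(2017, 10, 18))
        assert list(daily["n_flights"]) == [0, 2, 0]
        assert daily.iloc[1]["mean_flight_duration_min"] == pytest.approx(5.0)
        assert np.isnan(daily.iloc[0]["mean_flight_duration_min"])

    def test_flight_attributed_to_departure_date(self):
        events = flight("T1", at(16, 23, 30), 120)  # crosses midnight
        spans, _ = spans_for(events)
        daily = daily_series(spans, date(2017, 10, 15), date(2017, 10, 18))
        assert list(daily["n_flights"]) == [0, 1, 0]

    def test_simulated_shutdown_days_have_zero_flights(self):
        shutdown = (date(2017, 10, 17), date(2017, 10, 18))
        cfg = SimConfig(
            n_drones=60,
            start_date=date(2017, 10, 15),
            end_date=date(2017, 10, 25),
            zero_activity_dates=shutdown,
            seed=2,
        )
        reads, _ = simulate_traffic(cfg)
        events, _ = detect_events(reads)
        spans = build_spans(events, *cfg.window())
        daily = daily_series(spans, cfg.start_date, cfg.end_date)
        by_date = dict(zip(daily["date"], daily["n_flights"]))
        assert all(by_date[d.isoformat()] == 0 for d in shutdown)
        assert sum(by_date.values()) > 0
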