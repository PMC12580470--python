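"""Independence filtering, trap days, and effort classification."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from huntshift import events

T0 = datetime(2021, 6, 1, 12, 0, tzinfo=timezone.utc)


def _records(offsets_s, camera="c1", label="human"):
    return pd.DataFrame(
        {
            "camera_id": camera,
            "timestamp": [T0 + timedelta(seconds=float(s)) for s in offsets_s],
            "class_label": label,
        }
    )


def brute_force_events(times_s, threshold):
    """Oracle: scan sorted times; gap >= threshold starts a new event."""
    ts = sorted(times_s)
    if not ts:
        return []
    starts = [ts[0]]
    prev = ts[0]
    for t in ts[1:]:
        if t - prev >= threshold:
            starts.append(t)
        prev = t
    return starts


class TestFilterIndependent:
    def test_record_to_record_chaining(self):
        # 0, 4, 9 s with an 8 s threshold: both gaps < 8 so one event
        out = events.filter_independent(_records([0, 4, 9]), 8)
        assert len(out) == 1
        assert out.loc[0, "n_triggers"] == 3
        assert out.loc[0, "event_time"] == T0

    def test_gap_at_threshold_starts_new_event(self):
        out = events.filter_independent(_records([0, 301]), 300)
        assert len(out) == 2

    def test_burst_collapses(self):
        out = events.filter_independent(_records([0, 2, 4, 6, 8]), 8)
        assert len(out) == 1

    def test_keys_are_independent(self):
        df = pd.concat(
            [_records([0, 4], camera="c1"), _records([0, 4], camera="c2")],
            ignore_index=True,
        )
        out = events.filter_independent(df, 8)
        assert len(out) == 2

    @given(
        st.lists(st.integers(min_value=0, max_value=3600), min_size=0, max_size=500),
        st.sampled_from([8.0, 60.0, 300.0]),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, offsets, threshold):
        out = events.filter_independent(_records(offsets), threshold)
        expected = brute_force_events(offsets, threshold)
        got = [(t - T0).total_seconds() for t in out["event_time"]]
        assert got == expected

    @given(st.lists(st.integers(min_value=0, max_value=7200), min_size=1, max_size=300))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, offsets):
        once = events.filter_independent(_records(offsets), 300)
        again = events.filter_independent(
            once.rename(columns={"event_time": "timestamp"}), 300
        )
        assert list(again["event_time"]) == list(once["event_time"])
        assert len(once) <= len(offsets)


class TestReadDetections:
    def test_roundtrip_and_rejects(self, tmp_path):
        p = tmp_path / "det.csv"
        p.write_text(
            "camera_id,timestamp,class_label\n"
            "c1,2021-06-01T12:00:00+00:00,human\n"
            "c1,not-a-date,human\n"
            "c2,2021-06-01T13:00:00+01:00,red_deer\n"
        )
        out = events.read_detections(p)
        assert len(out) == 2
        assert str(out["timestamp"].dt.tz) == "UTC"

    def test_missing_column_is_hard_error(self, tmp_path):
        p = tmp_path / "det.csv"
        p.write_text("timestamp,class_label\n2021-06-01T12:00:00+00:00,human\n")
        with pytest.raises(ValueError, match="camera_id"):
            events.read_detections(p)


class TestEffortClassification:
    def test_boundary_rules(self):
        assert events.classify_shares([12, 88]) == ["high", "high"]
        assert events.classify_shares([5, 95]) == ["medium", "high"]
        assert events.classify_shares([4.9, 95.1]) == ["low", "high"]

    def test_uniform_weights_all_medium(self):
        assert events.classify_shares([1] * 12) == ["medium"] * 12

    def test_single_loaded_month(self):
        labels = events.classify_shares([0, 0, 100, 0])
        assert labels == ["low", "low", "high", "low"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            events.classify_shares([0, 0, 0])

    def test_two_high_seasons_pool_into_one_stratum(self):
        months = pd.date_range("2020-11-01", "2021-12-01", freq="MS").date
        counts = {m: (20 if m.month in (10, 11, 12, 1) else (7 if m.month in (6, 7, 8, 9) else 2)) for m in months}
        cal = events.classify_effort(counts)
        assert cal.windows("high") == [
            (date(2020, 11, 1), date(2021, 1, 31)),
            (date(2021, 10, 1), date(2021, 12, 31)),
        ]
        assert cal.stratum_of(date(2020, 12, 15)) == "high"
        assert cal.stratum_of(date(2021, 4, 2)) == "low"
        assert cal.stratum_of(date(2021, 7, 2)) == "medium"


def _deployment(start, end, exclusions):
    return pd.DataFrame(
        [
            {
                "camera_id": "c1", "location_id": "L1", "placement": "trail",
                "lat": 49.0, "lon": 13.4, "in_hunting_zone": True,
                "dist_hunting_zone_m": 0.0, "vis50": 0.5, "vis70": 0.8, "vis140": 0.9,
                "start": start, "end": end, "exclusions": exclusions,
            }
        ]
    )


class TestTrapDays:
    @pytest.fixture
    def june_calendar(self):
        return events.EffortCalendar(
            months=[date(2021, 6, 1)], counts=[10.0], labels=["medium"]
        )

    def test_full_month_no_exclusions(self, june_calendar):
        dep = _deployment(date(2021, 6, 1), date(2021, 6, 30), [])
        td = events.compute_trap_days(dep, june_calendar)
        assert td.loc[0, "n_active_days"] == 30

    def test_exclusions_subtract(self, june_calendar):
        dep = _deployment(
            date(2021, 6, 1), date(2021, 6, 30), [(date(2021, 6, 10), date(2021, 6, 14))]
        )
        td = events.compute_trap_days(dep, june_calendar)
        assert td.loc[0, "n_active_days"] == 25

    def test_overlapping_exclusions_count_once(self, june_calendar):
        # days 1-5 and 4-8: union is 8 days, not 10
        dep = _deployment(
            date(2021, 6, 1), date(2021, 6, 30),
            [(date(2021, 6, 1), date(2021, 6, 5)), (date(2021, 6, 4), date(2021, 6, 8))],
        )
        td = events.compute_trap_days(dep, june_calendar)
        assert td.loc[0, "n_active_days"] == 22

    def test_random_exclusions_match_interval_union_oracle(self, june_calendar):
        rng = np.random.default_rng(7)
        for _ in range(20):
            iv = []
            for _k in range(rng.integers(0, 5)):
                a = int(rng.integers(1, 28))
                b = min(28, a + int(rng.integers(0, 6)))
                iv.append((date(2021, 6, a), date(2021, 6, b)))
            dep = _deployment(date(2021, 6, 1), date(2021, 6, 30), iv)
            td = events.compute_trap_days(dep, june_calendar)
            union = set()
            for a, b in iv:
                d = a
                while d <= b:
                    union.add(d)
                    d += timedelta(days=1)
            assert td.loc[0, "n_active_days"] == 30 - len(union)

    def test_strata_sum_to_total_active_days(self, study, sim_config):
        cal = study["calendar"]
        td = events.compute_trap_days(study["deployments"], cal)
        total = td.groupby("camera_id")["n_active_days"].sum()
        n_days = (sim_config.study_end - sim_config.study_start).days + 1
        for _, cam in study["deployments"].iterrows():
            excluded = sum((b - a).days + 1 for a, b in cam["exclusions"])
            assert total[cam["camera_id"]] == n_days - excluded
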