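from datetime import datetime, time

import numpy as np
import pandas as pd
import pytest

from cgmdepth import (
    ClockWindow,
    Intervention,
    InterventionSchedule,
    SyntheticConfig,
    extract_clock_window,
    generate_trace,
    inject_gaps,
    nights_of,
    split_by_intervention,
)
from cgmdepth.windows import NOCTURNAL_WINDOW, UNASSIGNED_LABEL

from conftest import START, make_trace


class TestClockWindow:
    def test_parse(self):
        w = ClockWindow.parse("01:00-05:00")
        assert w.start == time(1, 0) and w.end == time(5, 0)
        with pytest.raises(ValueError):
            ClockWindow.parse("1am to 5am")

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            ClockWindow(time(3, 0), time(3, 0))

    def test_wrapping_window_duration_and_mask(self):
        w = ClockWindow(time(22, 0), time(6, 0))
        assert w.duration_minutes() == 8 * 60
        times = pd.DatetimeIndex(["2021-03-01 23:00", "2021-03-02 03:00", "2021-03-02 12:00"])
        np.testing.assert_array_equal(w.mask(times), [True, True, False])


class TestExtractClockWindow:
    def test_four_days_give_192_nocturnal_samples(self, four_day_trace):
        assert len(extract_clock_window(four_day_trace, NOCTURNAL_WINDOW)) == 192

    def test_one_day_gives_48(self):
        trace = generate_trace(SyntheticConfig(duration_h=24.0))
        assert len(extract_clock_window(trace, NOCTURNAL_WINDOW)) == 48

    def test_daytime_trace_yields_empty(self):
        trace = make_trace([5.0] * 12, start=datetime(2021, 3, 1, 6, 0), cadence_min=60)
        assert len(extract_clock_window(trace, NOCTURNAL_WINDOW)) == 0

    def test_idempotent(self, four_day_trace):
        once = extract_clock_window(four_day_trace, NOCTURNAL_WINDOW)
        twice = extract_clock_window(once, NOCTURNAL_WINDOW)
        assert once.equals(twice, tol=0)

    def test_half_open_boundary(self):
        # samples exactly at 01:00 included, exactly at 05:00 excluded
        trace = make_trace([5.0, 5.0], start=datetime(2021, 3, 1, 1, 0), cadence_min=240)
        sub = extract_clock_window(trace, NOCTURNAL_WINDOW)
        assert len(sub) == 1 and sub.times[0].hour == 1


class TestSplitByIntervention:
    def test_single_covering_intervention_is_identity(self, four_day_trace):
        sched = InterventionSchedule(
            [Intervention("all", four_day_trace.start, four_day_trace.end + pd.Timedelta(minutes=5))]
        )
        groups = split_by_intervention(four_day_trace, sched)
        assert set(groups) == {"all"}
        assert groups["all"].equals(four_day_trace, tol=0)

    def test_two_abutting_interventions_split_at_midnight(self):
        trace = generate_trace(SyntheticConfig(duration_h=48.0, start=START))
        midnight = pd.Timestamp(START) + pd.Timedelta(days=1)
        sched = InterventionSchedule(
            [
                Intervention("day1", pd.Timestamp(START), midnight),
                Intervention("day2", midnight, midnight + pd.Timedelta(days=1)),
            ]
        )
        groups = split_by_intervention(trace, sched)
        assert len(groups["day1"]) == 288 and len(groups["day2"]) == 288
        # boundary sample (midnight itself) belongs to the later segment
        assert groups["day2"].start == midnight

    def test_partition_sizes_sum_to_trace_length(self, four_day_trace):
        cut = pd.Timestamp(START) + pd.Timedelta(hours=30)
        sched = InterventionSchedule(
            [Intervention("a", pd.Timestamp(START) + pd.Timedelta(hours=7), cut)]
        )
        groups = split_by_intervention(four_day_trace, sched)
        assert sum(len(g) for g in groups.values()) == len(four_day_trace)
        assert UNASSIGNED_LABEL in groups

    def test_overlapping_interventions_rejected(self, four_day_trace):
        sched = InterventionSchedule(
            [
                Intervention("a", "2021-03-01", "2021-03-02 12:00"),
                Intervention("b", "2021-03-02", "2021-03-03"),
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            split_by_intervention(four_day_trace, sched)

    def test_schedule_io_roundtrip(self, tmp_path):
        yaml_path = tmp_path / "sched.yaml"
        yaml_path.write_text(
            "patient_id: p1\n"
            "interventions:\n"
            "  - {label: a, start: 2021-03-01 00:00, end: 2021-03-02 00:00, dose_text: 5 mg}\n"
            "  - {label: b, start: 2021-03-02 00:00, end: 2021-03-03 00:00}\n"
        )
        sched = InterventionSchedule.from_yaml(yaml_path)
        assert sched.labels == ["a", "b"]
        assert sched.interventions[0].dose_text == "5 mg"


class TestFillSingleGaps:
    def test_one_missing_sample_interpolated(self):
        from cgmdepth import fill_single_gaps

        trace = generate_trace(SyntheticConfig(duration_h=2.0, start=START))
        hole = pd.Timestamp(START) + pd.Timedelta(minutes=30)
        gapped = inject_gaps(trace, [(hole, hole + pd.Timedelta(minutes=5))])
        filled = fill_single_gaps(gapped)
        assert len(filled) == len(trace)
        i = list(filled.times).index(hole)
        assert filled.values[i] == pytest.approx(
            0.5 * (filled.values[i - 1] + filled.values[i + 1])
        )

    def test_long_gaps_left_alone(self):
        from cgmdepth import fill_single_gaps

        trace = generate_trace(SyntheticConfig(duration_h=2.0, start=START))
        hole = pd.Timestamp(START) + pd.Timedelta(minutes=30)
        gapped = inject_gaps(trace, [(hole, hole + pd.Timedelta(minutes=15))])
        filled = fill_single_gaps(gapped)
        assert len(filled) == len(gapped)  # 3-sample hole is not resampled


class TestNightsOf:
    def test_seven_complete_days(self):
        trace = generate_trace(SyntheticConfig(duration_h=7 * 24.0))
        nights = nights_of(trace, NOCTURNAL_WINDOW)
        assert len(nights) == 7
        assert all(nt.n == 48 and nt.complete for nt in nights)
        assert all(nt.n <= NOCTURNAL_WINDOW.duration_minutes() / trace.cadence_min for nt in nights)

    def test_missing_night_absent(self):
        trace = generate_trace(SyntheticConfig(duration_h=3 * 24.0, start=START))
        night2 = pd.Timestamp(START) + pd.Timedelta(days=1, hours=1)
        gapped = inject_gaps(trace, [(night2, night2 + pd.Timedelta(hours=4))])
        nights = nights_of(gapped, NOCTURNAL_WINDOW)
        assert len(nights) == 2
        assert pd.Timestamp(START) + pd.Timedelta(days=1) not in [nt.date for nt in nights]

    def test_partial_night_flagged_but_eligible(self):
        trace = generate_trace(SyntheticConfig(duration_h=24.0, start=START))
        hole = pd.Timestamp(START) + pd.Timedelta(hours=1)
        gapped = inject_gaps(trace, [(hole, hole + pd.Timedelta(minutes=40))])  # 8 samples
        (night,) = nights_of(gapped, NOCTURNAL_WINDOW)
        assert night.n == 40
        assert not night.complete
        assert night.eligible(0.8)  # 40/48 = 83%
        assert not night.eligible(0.9)

    def test_wrapping_window_attributes_morning_to_previous_date(self):
        trace = generate_trace(SyntheticConfig(duration_h=48.0, start=START))
        nights = {nt.date: nt for nt in nights_of(trace, ClockWindow(time(22, 0), time(2, 0)))}
        # the trace's 00:00-02:00 head belongs to the previous (off-trace) date;
        # the only complete night starts 22:00 on day 1 and runs into day 2
        full = nights[pd.Timestamp(START)]
        assert full.n == 48 and full.complete  # 4 h at 5 min
        head = nights[pd.Timestamp(START) - pd.Timedelta(days=1)]
        assert head.n == 24 and not head.complete
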