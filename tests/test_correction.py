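import datetime as dt

import numpy as np
import pytest

from actirhythm import (
    CareEventTemplate,
    EndogenousRhythmSpec,
    EventLog,
    EventRecord,
    EventType,
    PaddingPolicy,
    UncorrectableSeriesError,
    ValidationError,
    build_removal_intervals,
    correct_series,
    downsample_to_minutes,
    generate_patient,
    impute_interval,
    removed_fraction_report,
)

from conftest import make_series

NINE = dt.datetime(2021, 3, 1, 9, 0)


def interval_log(etype, start_hm, end_hm, day=dt.date(2021, 3, 1)):
    mk = lambda hm: dt.datetime.combine(day, dt.time(*hm))
    return EventRecord(etype, mk(start_hm), mk(end_hm))


class TestDownsample:
    def test_sum_of_two_second_epochs(self, midnight):
        raw = make_series(np.ones(60), epoch_seconds=2)
        out = downsample_to_minutes(raw)
        assert out.epoch_seconds == 60
        np.testing.assert_array_equal(out.values, [30.0, 30.0])

    def test_all_zero(self):
        out = downsample_to_minutes(make_series(np.zeros(120), epoch_seconds=1))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_ramp_arithmetic_series(self):
        out = downsample_to_minutes(make_series(np.arange(1, 61), epoch_seconds=1))
        assert out.values.tolist() == [1830.0]

    def test_trailing_partial_minute_dropped(self):
        out = downsample_to_minutes(make_series(np.ones(90), epoch_seconds=1))
        assert out.n_epochs == 1

    def test_mean_aggregator(self):
        out = downsample_to_minutes(make_series(np.ones(60), epoch_seconds=2), "mean")
        np.testing.assert_array_equal(out.values, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            downsample_to_minutes(make_series([], epoch_seconds=1))


class TestRemovalIntervals:
    def test_nursing_padded_five_minutes(self):
        series = make_series(np.zeros(180), start=NINE)  # 09:00-12:00
        log = EventLog("X", [interval_log(EventType.NURSING, (10, 0), (10, 20))])
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        assert iv.start == dt.datetime(2021, 3, 1, 9, 55)
        assert iv.end == dt.datetime(2021, 3, 1, 10, 25)
        assert iv.source_types == {EventType.NURSING}

    def test_visit_and_wheelchair_merge(self):
        series = make_series(np.zeros(12 * 60), start=NINE)  # 09:00-21:00
        log = EventLog(
            "X",
            [
                interval_log(EventType.VISIT, (14, 0), (15, 0)),
                interval_log(EventType.WHEELCHAIR, (14, 50), (15, 30)),
            ],
        )
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        assert iv.start == dt.datetime(2021, 3, 1, 13, 50)
        assert iv.end == dt.datetime(2021, 3, 1, 15, 40)
        assert iv.source_types == {EventType.VISIT, EventType.WHEELCHAIR}

    def test_point_events_produce_no_removal(self):
        series = make_series(np.zeros(60), start=NINE)
        log = EventLog("X", [EventRecord(EventType.MEDICATION, NINE)])
        assert build_removal_intervals(log, PaddingPolicy(), series) == []

    def test_event_outside_span_ignored(self):
        series = make_series(np.zeros(60), start=NINE)
        log = EventLog("X", [interval_log(EventType.VISIT, (15, 0), (16, 0))])
        assert build_removal_intervals(log, PaddingPolicy(), series) == []

    def test_outward_snap_to_epoch_grid(self):
        series = make_series(np.zeros(120), start=NINE)
        log = EventLog(
            "X",
            [
                EventRecord(
                    EventType.THERAPY,  # zero pad: snap shows through
                    dt.datetime(2021, 3, 1, 9, 10, 30),
                    dt.datetime(2021, 3, 1, 9, 20, 30),
                )
            ],
        )
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        assert iv.start == dt.datetime(2021, 3, 1, 9, 10)
        assert iv.end == dt.datetime(2021, 3, 1, 9, 21)


class TestImputeInterval:
    def test_constant_series_imputes_constant(self):
        series = make_series(np.full(60, 7.0), start=NINE)
        log = EventLog("X", [interval_log(EventType.THERAPY, (9, 20), (9, 30))])
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        values, _ = impute_interval(series, iv)
        np.testing.assert_array_equal(values, 7.0)

    def test_two_sided_medians(self):
        # 10 min of 2,4,...,20 | 4-min gap | 10 min of 100
        vals = np.concatenate([np.arange(2, 22, 2), [999] * 4, [100.0] * 10])
        series = make_series(vals, start=NINE)
        log = EventLog("X", [interval_log(EventType.THERAPY, (9, 10), (9, 14))])
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        values, prov = impute_interval(series, iv)
        np.testing.assert_array_equal(values, [11.0, 11.0, 100.0, 100.0])
        assert prov.tolist() == ["before", "before", "after", "after"]

    def test_boundary_falls_back_to_following_side(self):
        vals = np.concatenate([[999] * 4, [50.0] * 20])
        series = make_series(vals, start=NINE)
        log = EventLog("X", [interval_log(EventType.THERAPY, (9, 0), (9, 4))])
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        values, prov = impute_interval(series, iv)
        np.testing.assert_array_equal(values, 50.0)
        assert set(prov) == {"after"}

    def test_odd_interval_gives_extra_epoch_to_preceding(self):
        vals = np.concatenate([[1.0] * 10, [999] * 5, [9.0] * 10])
        series = make_series(vals, start=NINE)
        log = EventLog("X", [interval_log(EventType.THERAPY, (9, 10), (9, 15))])
        (iv,) = build_removal_intervals(log, PaddingPolicy(), series)
        values, _ = impute_interval(series, iv)
        np.testing.assert_array_equal(values, [1, 1, 1, 9, 9])


class TestCorrectSeries:
    def test_empty_log_is_identity(self):
        series = make_series(np.arange(100.0), start=NINE)
        out = correct_series(series, EventLog("X"))
        np.testing.assert_array_equal(out.series.values, series.values)
        assert out.removed_fraction == 0.0
        assert not out.removed.any()

    def test_mask_conservation(self):
        series = make_series(np.random.default_rng(0).uniform(0, 5, 240), start=NINE)
        log = EventLog("X", [interval_log(EventType.NURSING, (9, 30), (9, 50))])
        out = correct_series(series, log)
        assert out.removed.sum() + (~out.removed).sum() == series.n_epochs
        assert out.removed_fraction == pytest.approx(out.removed.mean())

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        series = make_series(rng.uniform(0, 20, 12 * 60), start=NINE)
        log = EventLog(
            "X",
            [
                interval_log(EventType.NURSING, (10, 0), (10, 20)),
                interval_log(EventType.VISIT, (14, 0), (15, 0)),
            ],
        )
        once = correct_series(series, log)
        twice = correct_series(once.series, log)
        np.testing.assert_array_equal(once.series.values, twice.series.values)
        np.testing.assert_array_equal(once.removed, twice.removed)

    def test_constant_series_invariant(self):
        series = make_series(np.full(240, 3.0), start=NINE)
        log = EventLog("X", [interval_log(EventType.WHEELCHAIR, (10, 0), (11, 0))])
        out = correct_series(series, log)
        np.testing.assert_array_equal(out.series.values, 3.0)

    def test_imputed_values_within_context_extrema(self):
        rng = np.random.default_rng(2)
        series = make_series(rng.uniform(0, 50, 240), start=NINE)
        log = EventLog("X", [interval_log(EventType.NURSING, (10, 0), (10, 30))])
        out = correct_series(series, log)
        sl = out.intervals[0].epoch_slice(series)
        clean = series.values[~out.removed]
        assert out.series.values[sl].min() >= clean.min()
        assert out.series.values[sl].max() <= clean.max()

    def test_mask_covers_padded_true_windows_of_simulation(self):
        spec = EndogenousRhythmSpec(10, 3, noise_sd=2)
        templates = [
            CareEventTemplate(EventType.NURSING, 8.0, 30, 60, jitter_sd_minutes=5),
            CareEventTemplate(EventType.VISIT, 14.0, 60, 40, jitter_sd_minutes=10),
        ]
        p = generate_patient(spec, templates, days=4, seed=11)
        out = correct_series(p.recorded, p.log)
        # pads (5 min nursing, 10 min visit) cover the 3-min log latency, so
        # every epoch receiving passive activity must be masked
        for start, end, _ in p.true_events:
            i0 = int(np.ceil(p.recorded.epoch_index(start)))
            i1 = int(np.ceil(p.recorded.epoch_index(end)))
            assert out.removed[i0:i1].all()

    def test_near_total_removal_mirrors_patient_exclusion(self):
        series = make_series(np.ones(24 * 60), start=NINE)
        log = EventLog(
            "X",
            [
                EventRecord(
                    EventType.VISIT, NINE, NINE + dt.timedelta(hours=23)
                )
            ],
        )
        with pytest.raises(UncorrectableSeriesError, match="uncorrectable"):
            correct_series(series, log)

    def test_extra_intervals_stand_in_for_manual_screening(self):
        series = make_series(np.arange(120.0), start=NINE)
        manual = [(dt.datetime(2021, 3, 1, 9, 30), dt.datetime(2021, 3, 1, 9, 40))]
        out = correct_series(series, EventLog("X"), extra_intervals=manual)
        assert out.removed[30:40].all()
        assert out.removed.sum() == 10


class TestRemovedFractionReport:
    def test_no_events_zero(self):
        series = make_series(np.ones(100), start=NINE)
        report = removed_fraction_report(correct_series(series, EventLog("X")))
        assert report["overall"] == 0.0
        assert report["per_type"] == {}

    def test_half_removed(self):
        series = make_series(np.ones(120), start=NINE)
        log = EventLog("X", [interval_log(EventType.THERAPY, (9, 0), (10, 0))])
        report = removed_fraction_report(correct_series(series, log))
        assert report["overall"] == pytest.approx(0.5)
        assert report["per_type"] == {"therapy": pytest.approx(0.5)}

    def test_fraction_monotone_in_event_duration(self):
        fractions = []
        for minutes in (15, 30, 60):
            templates = [
                CareEventTemplate(EventType.NURSING, 9.0, minutes, 50.0),
                CareEventTemplate(EventType.NURSING, 15.0, minutes, 50.0),
            ]
            p = generate_patient(
                EndogenousRhythmSpec(10, 2, noise_sd=1), templates, days=3, seed=0
            )
            out = correct_series(p.recorded, p.log)
            fractions.append(removed_fraction_report(out)["overall"])
        assert fractions[0] < fractions[1] < fractions[2]
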