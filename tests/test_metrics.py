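import datetime as dt
import math

import numpy as np
import pytest
from scipy import signal as ssig

from actirhythm import (
    Periodogram,
    ValidationError,
    day_night_means,
    extract_circadian_peak,
    interdaily_stability,
    intradaily_variability,
    lomb_scargle,
    summarize_series,
)
from actirhythm.metrics import _scargle_power

from conftest import make_series, sine_series


def hourly_series(values, **kw):
    return make_series(values, epoch_seconds=3600, **kw)


class TestInterdailyStability:
    def test_exactly_periodic_pattern_gives_one(self):
        day = np.random.default_rng(0).uniform(0, 10, 1440)
        s = make_series(np.tile(day, 5))
        assert interdaily_stability(s) == pytest.approx(1.0, abs=1e-12)

    def test_constant_is_undefined(self):
        s = make_series(np.full(3 * 1440, 4.0))
        assert math.isnan(interdaily_stability(s))

    def test_requires_two_days(self):
        with pytest.raises(ValidationError):
            interdaily_stability(make_series(np.random.default_rng(0).uniform(size=1440)))

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (3.5, 10.0)])
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, 7 * 24)
        s1 = hourly_series(x)
        s2 = hourly_series(a * x + b)
        assert interdaily_stability(s2) == pytest.approx(interdaily_stability(s1))

    def test_shift_by_full_day_invariant(self, midnight):
        x = np.random.default_rng(5).uniform(0, 5, 7 * 24)
        s1 = hourly_series(x, start=midnight)
        s2 = hourly_series(x, start=midnight + dt.timedelta(days=1))
        assert interdaily_stability(s1) == interdaily_stability(s2)
        assert intradaily_variability(s1) == intradaily_variability(s2)


class TestIntradailyVariability:
    def test_hourly_sine_is_smooth(self):
        s = sine_series(days=7, amplitude=5, epoch_minutes=60)
        iv = intradaily_variability(s)
        expected = 2 * (1 - math.cos(2 * math.pi / 24))
        assert iv == pytest.approx(expected, rel=0.05)
        assert iv < 0.1

    def test_alternating_sequence_is_ultradian(self):
        x = np.tile([1.0, 5.0], 84)  # N = 168 hourly bins
        iv = intradaily_variability(hourly_series(x))
        assert iv == pytest.approx(4.0 * 168 / 168, rel=1e-12)
        assert iv >= 3.9

    def test_constant_is_undefined(self):
        assert math.isnan(intradaily_variability(hourly_series(np.ones(48))))

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 7.0)])
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(6).uniform(0, 5, 100)
        assert intradaily_variability(hourly_series(a * x + b)) == pytest.approx(
            intradaily_variability(hourly_series(x))
        )


class TestLombScargle:
    def test_sine_24h_minute_sampling_peak(self):
        s = sine_series(days=7, period_hours=24.0, amplitude=5, noise_sd=1.0)
        pg = lomb_scargle(s, period_range_hours=(2.0, math.inf))
        peak = extract_circadian_peak(pg)
        assert peak.significant
        assert abs(peak.period_hours - 24.0) <= 24.0**2 / (100 * s.span_hours) + 1e-9
        assert pg.p_values[np.argmax(pg.normalized_power)] < 0.001

    def test_sine_25h_peak(self):
        s = sine_series(days=7, period_hours=25.0, amplitude=5, noise_sd=1.0)
        peak = extract_circadian_peak(lomb_scargle(s, period_range_hours=(2.0, math.inf)))
        grid_step = 25.0**2 / (100 * s.span_hours)
        assert abs(peak.period_hours - 25.0) <= grid_step + 1e-9
        # a true 25-h rhythm sits at the 1-h deviation boundary (to grid accuracy)
        assert peak.deviation_from_24h == pytest.approx(1.0, abs=grid_step + 1e-9)

    def test_constant_input_undefined_not_error(self):
        pg = lomb_scargle(hourly_series(np.ones(72)))
        assert np.all(np.isnan(pg.normalized_power))
        peak = extract_circadian_peak(pg)
        assert not peak.significant and not peak.is_circadian

    def test_matches_scipy_reference_exactly(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 100, 300))
        y = np.sin(2 * np.pi * t / 24) + rng.normal(0, 1, t.size)
        freqs = np.linspace(0.01, 0.45, 400)
        mine = _scargle_power(t, y, freqs)
        ref = ssig.lombscargle(t, y - y.mean(), 2 * np.pi * freqs)
        np.testing.assert_allclose(mine, ref, rtol=1e-9)

    def test_power_invariant_to_affine_rescale(self):
        s = sine_series(days=4, amplitude=4, epoch_minutes=30, noise_sd=0.5)
        pg1 = lomb_scargle(s)
        pg2 = lomb_scargle(s.with_values(3.0 * s.values + 10.0))
        np.testing.assert_allclose(pg1.normalized_power, pg2.normalized_power, rtol=1e-6)

    def test_amplitude_monotonicity_at_true_period(self):
        rng_seeds = range(10)
        amplitudes = [0.5, 1.0, 2.0, 4.0, 8.0]
        mean_power = []
        for amp in amplitudes:
            powers = []
            for seed in rng_seeds:
                s = sine_series(
                    days=7, amplitude=amp, mesor=10, epoch_minutes=60, noise_sd=2.0, seed=seed
                )
                pg = lomb_scargle(s, period_range_hours=(20, 30))
                i = np.argmin(np.abs(pg.periods_hours - 24.0))
                powers.append(pg.normalized_power[i])
            mean_power.append(np.mean(powers))
        assert all(b >= a for a, b in zip(mean_power, mean_power[1:]))

    def test_requires_three_distinct_timestamps(self):
        with pytest.raises(ValidationError):
            lomb_scargle((np.array([0.0, 1.0]), np.array([1.0, 2.0])))


class TestExtractPeak:
    @staticmethod
    def pg_from(periods, power, alpha=0.001, significant_idx=()):
        periods = np.asarray(periods, dtype=float)
        power = np.asarray(power, dtype=float)
        p = np.ones(power.size)
        p[list(significant_idx)] = alpha / 10
        return Periodogram(periods, power, p, ofac=1.0, alpha=alpha, n_indep_freq=1.0)

    def test_closest_to_24_rule(self):
        # significant local maxima at 23.5 h and 12.0 h
        pg = self.pg_from(
            [30, 23.5, 18, 12.0, 8],
            [1, 10, 1, 12, 1],
            significant_idx=[1, 3],
        )
        peak = extract_circadian_peak(pg)
        assert peak.period_hours == 23.5
        assert peak.deviation_from_24h == pytest.approx(0.5)
        assert peak.is_circadian

    def test_deviation_boundary_excluded(self):
        pg = self.pg_from([30, 22.5, 12], [1, 10, 1], significant_idx=[1])
        peak = extract_circadian_peak(pg)
        assert peak.deviation_from_24h == pytest.approx(1.5)
        assert not peak.is_circadian

    def test_exactly_one_hour_deviation_not_circadian(self):
        pg = self.pg_from([30, 25.0, 12], [1, 10, 1], significant_idx=[1])
        assert not extract_circadian_peak(pg).is_circadian

    def test_no_significant_peak(self):
        pg = self.pg_from([30, 24, 12], [1, 2, 1], significant_idx=[])
        peak = extract_circadian_peak(pg)
        assert not peak.significant and math.isnan(peak.period_hours)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            periods = np.sort(rng.uniform(4, 40, 30))[::-1]
            power = rng.uniform(0, 15, 30)
            pvals = rng.uniform(0, 0.01, 30)
            pg = Periodogram(periods, power, pvals, 1.0, 0.001, 1.0)
            got = extract_circadian_peak(pg)
            # oracle: scan all interior strict local maxima with p < alpha
            best = None
            for i in range(1, 29):
                if power[i] > power[i - 1] and power[i] > power[i + 1] and pvals[i] < 0.001:
                    if best is None or abs(periods[i] - 24) < abs(periods[best] - 24):
                        best = i
            if best is None:
                assert not got.significant
            else:
                assert got.period_hours == periods[best]


class TestDayNight:
    def test_constant(self):
        s = make_series(np.full(1440, 5.0))
        dn = day_night_means(s)
        assert dn.mean_day == 5.0 and dn.mean_night == 5.0

    def test_day_only_activity(self, midnight):
        sod = make_series(np.zeros(1440)).seconds_of_day()
        values = np.where((sod >= 7 * 3600) & (sod < 21 * 3600), 10.0, 0.0)
        dn = day_night_means(make_series(values))
        assert dn.mean_day == 10.0 and dn.mean_night == 0.0

    def test_epoch_starting_at_day_end_is_night(self, midnight):
        start = midnight.replace(hour=21, minute=0)
        s = make_series([8.0, 8.0], start=start)
        dn = day_night_means(s)
        assert math.isnan(dn.mean_day)
        assert dn.mean_night == 8.0


class TestSummarize:
    def test_strong_sine_summary(self):
        s = sine_series(days=7, amplitude=8, mesor=10, acrophase_hours=14.0, noise_sd=0.5)
        summary = summarize_series(s)
        assert summary.IS > 0.9
        assert summary.IV < 0.2
        assert summary.peak.is_circadian
        assert summary.day_night.mean_day > summary.day_night.mean_night

    def test_pure_noise_summary(self):
        rng = np.random.default_rng(9)
        s = hourly_series(np.abs(rng.normal(10, 3, 7 * 24)))
        summary = summarize_series(s)
        assert summary.IS < 0.5
        assert 1.5 < summary.IV < 2.5
        assert not summary.peak.is_circadian

    def test_constant_summary_undefined_metrics(self):
        s = make_series(np.full(3 * 1440, 2.0))
        summary = summarize_series(s)
        assert math.isnan(summary.IS) and math.isnan(summary.IV)
        assert not summary.peak.significant
        assert summary.day_night.mean_day == summary.day_night.mean_night
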