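"""Degree-day accumulation, hatch forecasting and window back-calculation."""

import datetime as dt
import math

import numpy as np
import pytest

from ovitherm.cohort import FieldRecord, TemperatureSeries
from ovitherm.errors import ParameterError, RangeError, WindowError
from ovitherm.phenology import (
    StageDurations,
    accumulate_degree_days,
    estimate_oviposition_window,
    forecast_hatch,
    weekly_mean_series,
)
from ovitherm.synthetic import generate_field_records, generate_temperature_series


def _constant_series(temp, n_days=400, start=dt.date(2019, 8, 1), area="A"):
    return TemperatureSeries(
        area,
        tuple(start + dt.timedelta(days=i) for i in range(n_days)),
        (float(temp),) * n_days,
    )


class TestWeeklyMeans:
    def test_constant_input_constant_output(self):
        series = _constant_series(10.0, n_days=15 * 365)
        out = weekly_mean_series(series, years=15)
        assert all(t == pytest.approx(10.0) for t in out.tmean_c)

    def test_two_years_average(self):
        # week 1 of year one at 8 °C, week 1 of year two at 12 °C -> mean 10
        start = dt.date(2018, 1, 1)
        n = 2 * 365
        temps = []
        for i in range(n):
            d = start + dt.timedelta(days=i)
            base = 8.0 if d.year == 2018 else 12.0
            temps.append(base)
        series = TemperatureSeries("A", tuple(start + dt.timedelta(days=i) for i in range(n)), tuple(temps))
        out = weekly_mean_series(series, years=2)
        assert out.tmean_c[0] == pytest.approx(10.0)

    def test_sinusoid_within_one_weekly_step(self):
        series = generate_temperature_series(
            "A", dt.date(2016, 1, 1), 4 * 365, annual_mean=14.0,
            annual_amplitude=9.0, noise_sd=0.0,
        )
        out = weekly_mean_series(series, years=4)
        # weekly flattening can deviate by at most the within-week swing
        max_daily_step = 9.0 * 2 * math.pi / 365.25
        for d, t in zip(out.dates, out.tmean_c):
            assert abs(t - series.temperature_on(d)) <= 7 * max_daily_step


class TestDegreeDays:
    def test_constant_arithmetic(self):
        series = _constant_series(8.0)
        dd = accumulate_degree_days(series, 3.4, series.start)
        assert dd.daily_dd[0] == pytest.approx(4.6)
        assert dd.cumulative_dd[9] == pytest.approx(46.0)

    def test_below_threshold_accumulates_nothing(self):
        series = _constant_series(2.0)
        dd = accumulate_degree_days(series, 3.4, series.start)
        assert dd.cumulative_dd[-1] == 0.0

    def test_matches_brute_force_sum(self):
        series = generate_temperature_series("A", dt.date(2019, 9, 1), 120, seed=4)
        t0 = 3.4
        dd = accumulate_degree_days(series, t0, dt.date(2019, 9, 10))
        start = series.index_of(dt.date(2019, 9, 10))
        brute = 0.0
        for i, cum in enumerate(dd.cumulative_dd):
            brute += max(0.0, series.tmean_c[start + i] - t0)
            assert cum == pytest.approx(brute, abs=1e-9)

    def test_out_of_range_start_rejected(self):
        series = _constant_series(8.0, n_days=10)
        with pytest.raises(RangeError):
            accumulate_degree_days(series, 3.4, series.start - dt.timedelta(days=1))


class TestForecast:
    def test_constant_temperature_closed_form(self):
        series = _constant_series(20.0)
        fc = forecast_hatch(series, series.start, 3.40, 230.83)
        assert (fc.hatch_date - fc.lay_date).days == math.ceil(230.83 / 16.6)
        assert fc.dd_at_hatch >= 230.83
        assert not fc.horizon_exhausted

    @pytest.mark.parametrize("temp,t0,k", [(8.0, 3.4, 230.8), (12.0, 3.82, 209.05),
                                           (25.0, 3.3, 246.14), (6.1, 3.4, 100.0)])
    def test_ceil_identity_over_parameter_grid(self, temp, t0, k):
        series = _constant_series(temp)
        fc = forecast_hatch(series, series.start, t0, k)
        assert (fc.hatch_date - fc.lay_date).days == math.ceil(k / (temp - t0))

    def test_no_accumulation_exhausts_horizon(self):
        series = _constant_series(3.4, n_days=60)
        fc = forecast_hatch(series, series.start, 3.4, 230.83)
        assert fc.horizon_exhausted and fc.hatch_date is None

    def test_early_october_lay_hatches_in_about_two_weeks(self):
        # autumn series with Ebro-like climatology, medium-regime parameters
        series = generate_temperature_series("A", dt.date(2019, 8, 1), 200, seed=1)
        lay = dt.date(2019, 10, 3)
        fc = forecast_hatch(series, lay, 3.40, 230.83)
        assert 11 <= (fc.hatch_date - lay).days <= 21

    def test_hatch_monotone_in_lay_date(self):
        series = generate_temperature_series("A", dt.date(2019, 9, 1), 250, seed=9)
        previous = None
        for offset in range(0, 90, 5):
            lay = series.start + dt.timedelta(days=offset)
            fc = forecast_hatch(series, lay, 3.40, 230.83)
            if fc.hatch_date is None:
                break
            if previous is not None:
                assert fc.hatch_date >= previous
            previous = fc.hatch_date

    def test_nonpositive_thermal_constant_rejected(self):
        series = _constant_series(20.0)
        with pytest.raises(ParameterError):
            forecast_hatch(series, series.start, 3.4, 0.0)


STAGES = StageDurations(13, 20, 12)  # 45 d egg stage at 8 °C


class TestOvipositionWindow:
    def test_first_larva_back_dating(self):
        records = [
            FieldRecord(dt.date(2018, 12, 20), "A", "larva", 2),
            FieldRecord(dt.date(2018, 12, 1), "A", "egg_yellow", 5),
            FieldRecord(dt.date(2018, 10, 15), "A", "adult_reproductive", 4),
        ]
        window = estimate_oviposition_window(records, STAGES)
        assert window.start == dt.date(2018, 11, 5)  # 20 Dec - 45 d, no clipping
        assert window.end == dt.date(2018, 12, 1)

    def test_start_clipped_to_first_reproductive_adult(self):
        records = [
            FieldRecord(dt.date(2018, 12, 20), "A", "larva", 2),
            FieldRecord(dt.date(2018, 12, 1), "A", "egg_yellow", 5),
            FieldRecord(dt.date(2018, 11, 20), "A", "adult_reproductive", 4),
        ]
        window = estimate_oviposition_window(records, STAGES)
        assert window.start == dt.date(2018, 11, 20)

    def test_blackhead_eggs_bound_start_without_larvae(self):
        records = [
            FieldRecord(dt.date(2018, 12, 20), "A", "egg_blackhead", 3),
            FieldRecord(dt.date(2019, 1, 10), "A", "egg_yellow", 2),
        ]
        window = estimate_oviposition_window(records, STAGES)
        # lay no later than 20 Dec - (yellow + brown) = 20 Dec - 33 d
        assert window.start == dt.date(2018, 12, 20) - dt.timedelta(days=33)
        assert window.end == dt.date(2019, 1, 10)

    def test_undeterminable_without_qualifying_records(self):
        records = [FieldRecord(dt.date(2018, 12, 20), "A", "egg_brown", 3)]
        with pytest.raises(WindowError):
            estimate_oviposition_window(records, STAGES)

    def test_evidence_intervals_overlap_window(self):
        records = [
            FieldRecord(dt.date(2018, 12, 20), "A", "larva", 2),
            FieldRecord(dt.date(2018, 12, 1), "A", "egg_yellow", 5),
            FieldRecord(dt.date(2018, 10, 25), "A", "adult_reproductive", 4),
        ]
        window = estimate_oviposition_window(records, STAGES)
        for _record, (lo, hi) in window.evidence:
            assert lo <= window.end and hi >= window.start - dt.timedelta(days=STAGES.total)

    def test_recovery_on_synthetic_field_records(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            start = dt.date(2018, 10, 1) + dt.timedelta(days=int(rng.integers(0, 20)))
            end = start + dt.timedelta(days=int(rng.integers(60, 110)))
            sampling = [
                start + dt.timedelta(days=i)
                for i in range(0, (end - start).days + STAGES.total + 5, 3)
            ]
            records = generate_field_records((start, end), tuple(STAGES), sampling)
            window = estimate_oviposition_window(records, STAGES)
            assert start <= window.start <= start + dt.timedelta(days=3)
            assert end <= window.end <= end + dt.timedelta(days=STAGES.yellow)
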