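import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazemet.station_data import (
    FULL_DAY_HOURS, GR_HOURS, DailySeries, QCFlag, QCRanges, StationSeries,
    Variable, aggregate_daily, apply_exclusions, daily_ratio, gap_fill_linear,
    read_hourly_csv, screen_ranges, write_hourly_csv,
)
from conftest import make_series


class TestScreenRanges:
    @pytest.mark.parametrize("variable,value,expected", [
        (Variable.RH, 101.0, QCFlag.OUT_OF_RANGE),
        (Variable.PM25, 2.0, QCFlag.OUT_OF_RANGE),   # below detectable limit 3
        (Variable.T, 25.0, QCFlag.VALID),
        (Variable.T, -5.0, QCFlag.VALID),            # closed interval
        (Variable.T, 50.0, QCFlag.VALID),
        (Variable.WS, 50.1, QCFlag.OUT_OF_RANGE),
    ])
    def test_boundary_flags(self, variable, value, expected):
        s = screen_ranges(make_series([value], variable=variable))
        assert s.qc_flags.iloc[0] == expected

    def test_values_retained_not_dropped(self):
        s = screen_ranges(make_series([101.0, 50.0], variable=Variable.RH))
        assert s.values.iloc[0] == 101.0
        assert len(s.values) == 2

    def test_unknown_variable_errors(self):
        ranges = QCRanges({Variable.T: (-5, 50)})
        with pytest.raises(KeyError):
            screen_ranges(make_series([10.0], variable=Variable.RH), ranges)

    def test_visually_flagged_preserved(self):
        s = make_series([10.0, 20.0], variable=Variable.T)
        s = apply_exclusions(s, [s.values.index[0]])
        s = screen_ranges(s)
        assert s.qc_flags.iloc[0] == QCFlag.VISUALLY_FLAGGED
        assert s.qc_flags.iloc[1] == QCFlag.VALID

    @given(vals=st.lists(st.floats(-20, 120, allow_nan=False), min_size=1,
                         max_size=48))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, vals):
        s = screen_ranges(make_series(vals, variable=Variable.RH))
        s2 = screen_ranges(s)
        assert (s.qc_flags == s2.qc_flags).all()
        assert (s.values == s2.values).all()

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            QCRanges({Variable.T: (50, -5)})


class TestAggregateDaily:
    def test_half_valid_day_is_computed(self):
        vals = [40.0] * 12 + [np.nan] * 12
        d = aggregate_daily(make_series(vals, variable=Variable.PM25))
        assert d.values.iloc[0] == pytest.approx(40.0)
        assert d.valid_fraction.iloc[0] == pytest.approx(0.5)

    def test_below_half_valid_is_missing(self):
        vals = [40.0] * 11 + [np.nan] * 13
        d = aggregate_daily(make_series(vals, variable=Variable.PM25))
        assert np.isnan(d.values.iloc[0])
        assert d.valid_fraction.iloc[0] == pytest.approx(11 / 24)

    def test_radiation_window_mean(self):
        # hour labels 11..16 are clock hours 10..15
        vals = np.zeros(24)
        vals[10:16] = [200, 400, 600, 600, 400, 200]
        d = aggregate_daily(make_series(vals, variable=Variable.GR), GR_HOURS)
        assert d.values.iloc[0] == pytest.approx(400.0)

    def test_out_of_range_values_do_not_count_as_valid(self):
        vals = [101.0] * 13 + [50.0] * 11
        s = screen_ranges(make_series(vals, variable=Variable.RH))
        d = aggregate_daily(s)
        assert np.isnan(d.values.iloc[0])

    def test_constant_series_returns_constant(self):
        d = aggregate_daily(make_series([7.5] * 72, variable=Variable.T))
        assert np.allclose(d.values, 7.5)
        assert len(d.values) == 3

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            aggregate_daily(make_series([1.0]), window_hours=set())

    def test_wind_direction_vector_mean_across_north(self):
        # 350 and 10 degrees average to 0, not 180
        vals = [350.0, 10.0] * 12
        d = aggregate_daily(make_series(vals, variable=Variable.WD))
        ang = d.values.iloc[0]
        assert 0.0 <= ang < 360.0
        assert min(ang, 360.0 - ang) == pytest.approx(0.0, abs=1e-9)


class TestGapFill:
    def test_identity_regression(self):
        ref = make_series(np.linspace(10, 30, 200), variable=Variable.RH)
        tvals = ref.values.to_numpy().copy()
        tvals[150:160] = np.nan
        target = make_series(tvals, variable=Variable.RH, station="M6")
        filled = gap_fill_linear(target, ref)
        assert np.allclose(filled.values.iloc[150:160],
                           ref.values.iloc[150:160])
        assert (filled.qc_flags.iloc[150:160] == QCFlag.FILLED).all()

    def test_exact_linear_relation(self):
        x = np.linspace(5, 15, 150)
        ref = make_series(x, variable=Variable.RH)
        tv = 2 * x + 5
        tv[100] = np.nan
        target = make_series(tv, variable=Variable.RH)
        filled = gap_fill_linear(target, ref)
        assert filled.values.iloc[100] == pytest.approx(2 * x[100] + 5)

    def test_noisy_recovery_within_3se(self, rng):
        n = 500
        x = rng.uniform(20, 80, n)
        a_true, b_true, sigma = 3.0, 0.8, 1.0
        y = a_true + b_true * x + rng.normal(0, sigma, n)
        ref = make_series(x, variable=Variable.RH)
        yv = y.copy()
        yv[-10:] = np.nan
        target = make_series(yv, variable=Variable.RH)
        filled = gap_fill_linear(target, ref)
        # closed-form OLS on the same sample as the oracle
        X = np.column_stack([np.ones(n - 10), x[:-10]])
        beta, res, *_ = np.linalg.lstsq(X, y[:-10], rcond=None)
        pred = beta[0] + beta[1] * x[-10:]
        assert np.allclose(filled.values.iloc[-10:], pred)
        se_b = sigma / np.sqrt(((x[:-10] - x[:-10].mean()) ** 2).sum())
        assert abs(beta[1] - b_true) < 3 * se_b

    def test_valid_hours_never_altered(self, rng):
        x = rng.uniform(0, 50, 300)
        ref = make_series(x, variable=Variable.RH)
        tv = 0.9 * x + rng.normal(0, 1, 300)
        tv[50:70] = np.nan
        target = make_series(tv, variable=Variable.RH)
        filled = gap_fill_linear(target, ref)
        keep = np.ones(300, bool)
        keep[50:70] = False
        assert np.array_equal(filled.values.to_numpy()[keep], tv[keep])

    def test_insufficient_pairs_refuses(self):
        ref = make_series([1.0] * 10, variable=Variable.RH)
        target = make_series([np.nan] * 10, variable=Variable.RH)
        out = gap_fill_linear(target, ref)
        assert out.values.isna().all()


class TestDailyRatio:
    def test_constant_ratio(self):
        pm25 = make_series([30.0] * 24, variable=Variable.PM25)
        pm10 = make_series([60.0] * 24, variable=Variable.PM10)
        d = daily_ratio(pm25, pm10)
        assert d.values.iloc[0] == pytest.approx(0.5)

    def test_zero_pm10_hours_excluded(self):
        p25 = np.full(24, 30.0)
        p10 = np.full(24, 60.0)
        p10[:6] = 0.0
        d = daily_ratio(make_series(p25, variable=Variable.PM25),
                        make_series(p10, variable=Variable.PM10))
        # 18 ratio-valid hours of 0.5 still pass the 50% rule
        assert d.values.iloc[0] == pytest.approx(0.5)

    def test_two_valid_hours_is_missing(self):
        p25 = np.full(24, np.nan)
        p10 = np.full(24, np.nan)
        p25[:2], p10[:2] = [20.0, 30.0], [50.0, 50.0]
        d = daily_ratio(make_series(p25, variable=Variable.PM25),
                        make_series(p10, variable=Variable.PM10))
        assert np.isnan(d.values.iloc[0])

    def test_mean_of_ratios_not_ratio_of_means(self):
        # asymmetric fixture: the two statistics genuinely differ
        p25 = np.array([10.0, 90.0] * 12)
        p10 = np.array([100.0, 100.0] * 12)
        p10[1::2] = 120.0
        d = daily_ratio(make_series(p25, variable=Variable.PM25),
                        make_series(p10, variable=Variable.PM10))
        mean_of_ratios = np.mean(p25 / p10)
        ratio_of_means = p25.mean() / p10.mean()
        assert abs(mean_of_ratios - ratio_of_means) > 0.01
        assert d.values.iloc[0] == pytest.approx(mean_of_ratios)
        assert d.values.iloc[0] != pytest.approx(ratio_of_means)


class TestHourlyCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        s = make_series([1.0, np.nan, 3.0], variable=Variable.PM25,
                        station="P61", height=3.0)
        path = tmp_path / "hourly.csv"
        write_hourly_csv([s], path)
        back = read_hourly_csv(path)
        key = ("P61", "PM25", 3.0)
        assert key in back
        out = back[key]
        assert np.allclose(out.values.to_numpy(), s.values.to_numpy(),
                           equal_nan=True)
        assert out.qc_flags.iloc[1] == QCFlag.MISSING

    def test_non_hourly_index_rejected(self):
        idx = pd.DatetimeIndex(["2015-01-01 00:00", "2015-01-01 00:30"])
        with pytest.raises(ValueError):
            StationSeries.from_values("X", Variable.T, 2,
                                      pd.Series([1.0, 2.0], index=idx))
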