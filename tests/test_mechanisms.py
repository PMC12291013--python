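import numpy as np
import pandas as pd
import pytest

from fluxdrought import (
    cross_correlation_lag,
    diurnal_centroid,
    centroid_divergence,
    lag_attribution,
    moving_average,
)
from fluxdrought.mechanisms import monthly_zscore


class TestMovingAverage:
    def test_ramp_window_mean_hand_value(self):
        # centred 30-step window at index 30 covers values 16..45
        out = moving_average(np.arange(1.0, 61.0), 30)
        assert out.iloc[30] == pytest.approx(np.mean(np.arange(16.0, 46.0)))
        assert out.iloc[30] == pytest.approx(30.5)

    def test_incomplete_edges_masked(self):
        out = moving_average(np.arange(24.0), 12)
        assert out.isna().iloc[0] and out.isna().iloc[-1]
        assert out.notna().sum() == 24 - 12 + 1

    def test_commutes_with_affine_transform(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        a, b = 2.5, -7.0
        lhs = moving_average(a * x + b, 7)
        rhs = a * moving_average(x, 7) + b
        pd.testing.assert_series_equal(lhs, rhs)

    def test_constant_series_unchanged(self):
        out = moving_average(np.full(30, 4.2), 12)
        assert np.allclose(out.dropna(), 4.2)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), 12)


class TestMonthlyZscore:
    def _series(self, values, start="2015-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="MS")
        return pd.Series(values, index=idx, dtype=float)

    def test_hand_values_full_baseline(self):
        s = self._series([1, 3] * 6)  # mean 2, sample sd of [1,3]*6
        z = monthly_zscore(s)
        sd = np.std([1, 3] * 6, ddof=1)
        assert z.iloc[0] == pytest.approx((1 - 2) / sd)
        assert z.iloc[1] == pytest.approx((3 - 2) / sd)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_explicit_baseline_scales_outside_values(self):
        s = self._series(list(range(12)) + [100.0])
        z = monthly_zscore(s, baseline=("2015-01-01", "2015-12-01"))
        base = np.arange(12)
        expected = (100.0 - base.mean()) / base.std(ddof=1)
        assert z.iloc[-1] == pytest.approx(expected)

    def test_short_or_flat_baseline_rejected(self):
        with pytest.raises(ValueError):
            monthly_zscore(self._series(range(6)))
        with pytest.raises(ValueError):
            monthly_zscore(self._series([5.0] * 24))


class TestCrossCorrelationLag:
    def _idx(self, n):
        return pd.date_range("2014-01-01", periods=n, freq="MS")

    def test_identity_gives_lag_zero_r_one(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=60), index=self._idx(60))
        lc = cross_correlation_lag(s, s, max_lag=6)
        assert lc.lag == 0
        assert lc.peak_r == pytest.approx(1.0)
        assert lc.physiologically_meaningful

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(2)
        d = pd.Series(rng.normal(size=80), index=self._idx(80))
        r = d.shift(3)  # response trails driver by 3 months
        lc = cross_correlation_lag(d, r, max_lag=6)
        assert lc.lag == 3
        assert lc.peak_r > 0.99

    def test_leading_response_gets_negative_lag_and_flag(self):
        rng = np.random.default_rng(3)
        d = pd.Series(rng.normal(size=80), index=self._idx(80))
        lc = cross_correlation_lag(d, d.shift(-2), max_lag=6)
        assert lc.lag == -2
        assert not lc.physiologically_meaningful

    def test_null_pairs_rarely_exceed_half(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(100):
            d = pd.Series(rng.normal(size=80), index=self._idx(80))
            r = pd.Series(rng.normal(size=80), index=self._idx(80))
            if abs(cross_correlation_lag(d, r, max_lag=6).peak_r) < 0.5:
                hits += 1
        assert hits >= 95

    def test_too_short_overlap_rejected(self):
        s = pd.Series(np.arange(10.0), index=self._idx(10))
        with pytest.raises(ValueError):
            cross_correlation_lag(s, s, max_lag=6)

    def test_full_attribution_chain_recovers_lag(self):
        rng = np.random.default_rng(9)
        idx = self._idx(120)
        drv = pd.Series(rng.normal(size=120), index=idx)
        resp = drv.shift(2) + rng.normal(0, 0.2, 120)
        lc = lag_attribution(drv, resp, baseline=(idx[0], idx[47]),
                             window=(idx[24], idx[-24]), max_lag=6)
        assert lc.lag == 2


class TestDiurnalCentroid:
    def test_symmetric_day_is_noon(self):
        hours = np.arange(48) * 0.5 + 0.25
        flux = np.maximum(np.sin(np.pi * (hours - 7) / 10), 0.0)
        flux[(hours < 7) | (hours > 17)] = 0.0
        assert diurnal_centroid(flux) == pytest.approx(12.0, abs=1e-9)

    def test_point_mass_returns_its_hour(self):
        flux = np.zeros(48)
        flux[16] = 5.0  # midpoint 16*0.5 + 0.25 = 8.25
        assert diurnal_centroid(flux, min_steps=1) == pytest.approx(8.25)

    def test_two_step_weighted_mean(self):
        assert diurnal_centroid([3.0, 1.0], hours=[10.0, 14.0],
                                min_steps=1) == pytest.approx(11.0)

    def test_scaling_invariance_and_negative_floor(self):
        rng = np.random.default_rng(6)
        flux = rng.uniform(0, 10, 48)
        assert diurnal_centroid(5.0 * flux) == pytest.approx(diurnal_centroid(flux))
        # a negative excursion contributes zero weight, not negative weight
        spiked = flux.copy()
        spiked[20] = -50.0
        floored = flux.copy()
        floored[20] = 0.0
        assert diurnal_centroid(spiked) == pytest.approx(diurnal_centroid(floored))

    def test_empty_or_nocturnal_day_is_nan(self):
        assert np.isnan(diurnal_centroid(np.zeros(48)))
        night = np.zeros(48)
        night[0:4] = 3.0  # before 06:00
        assert np.isnan(diurnal_centroid(night))


def _halfhourly_frame(et_shift_drought_h=0.0):
    """Two years of half-hourly data; drought year 2018 may shift ET earlier."""
    idx = pd.date_range("2017-01-01", "2018-12-31 23:30", freq="30min")
    hours = idx.hour + idx.minute / 60.0 + 0.25
    shape = np.maximum(np.sin(np.pi * (hours - 7) / 10), 0.0)
    shape = np.where((hours >= 7) & (hours <= 17), shape, 0.0)
    drought = idx.year == 2018
    h_et = np.where(drought, hours + et_shift_drought_h, hours)
    et_shape = np.maximum(np.sin(np.pi * (h_et - 7) / 10), 0.0)
    et_shape = np.where((h_et >= 7) & (h_et <= 17), et_shape, 0.0)
    return pd.DataFrame({"GPP": shape, "ET": et_shape, "VPD": 1.0}, index=idx)


class TestCentroidDivergence:
    def test_identical_timing_gives_zero(self):
        out = centroid_divergence(_halfhourly_frame(0.0),
                                  ("2018-01-01", "2018-12-31"))
        assert set(out.index) == {"DJF", "MAM", "JJA", "SON"}
        assert np.allclose(out["divergence_h"], 0.0, atol=1e-9)

    def test_one_hour_earlier_et_detected(self):
        out = centroid_divergence(_halfhourly_frame(1.0),
                                  ("2018-01-01", "2018-12-31"))
        # ET shifted one hour earlier during the drought in every season
        assert np.allclose(out["divergence_h"], -1.0, atol=0.1)

    def test_sparse_season_is_nan(self):
        df = _halfhourly_frame(0.0)
        # blank almost all of pre-drought summer GPP
        mask = (df.index.year == 2017) & df.index.month.isin([1, 2, 12])
        df.loc[mask, "GPP"] = np.nan
        out = centroid_divergence(df, ("2018-01-01", "2018-12-31"))
        assert np.isnan(out.loc["DJF", "divergence_h"])
        assert np.isfinite(out.loc["JJA", "divergence_h"])

    def test_missing_column_rejected(self):
        df = _halfhourly_frame().drop(columns=["VPD"])
        with pytest.raises(ValueError, match="VPD"):
            centroid_divergence(df, ("2018-01-01", "2018-12-31"))
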