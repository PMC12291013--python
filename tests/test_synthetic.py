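import numpy as np
import pandas as pd
import pytest

from fluxdrought import (
    PRESETS,
    SiteScenario,
    generate_site,
    lagged_response_series,
    scenario_from_preset,
)
from fluxdrought.synthetic import (
    STUDY_GROUP_CLIMATE,
    ensemble_scenarios,
    disaggregate_diurnal,
    fluxes_from_water,
    generate_monthly_climate,
    monthly_to_daily,
    run_bucket,
)


def _quiet(preset="dry", **kw):
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("seed", 0)
    return scenario_from_preset(preset, **kw)


class TestMonthlyClimate:
    def test_flat_cycle_no_noise_is_constant_outside_drought(self):
        sc = _quiet(P_seasonal_amplitude=0.0, PET_seasonal_amplitude=0.0,
                    drought_years=())
        clim = generate_monthly_climate(sc)
        assert np.allclose(clim["P"], sc.P_mean / 12.0)
        assert np.allclose(clim["PET"], sc.PET_mean / 12.0)

    def test_long_run_mean_matches_target_within_5pct(self):
        sc = scenario_from_preset("dry", n_years=200, start_year=1900,
                                  drought_years=(), seed=3)
        clim = generate_monthly_climate(sc)
        assert clim["P"].sum() / 200 == pytest.approx(sc.P_mean, rel=0.05)
        assert clim["PET"].sum() / 200 == pytest.approx(sc.PET_mean, rel=0.05)

    def test_drought_years_scaled_by_multipliers(self):
        sc = _quiet(drought_years=(2018,), gy_start_month=1)
        clim = generate_monthly_climate(sc)
        for m in range(1, 13):
            ref_p = clim.loc[f"2015-{m:02d}-01", "P"]
            ref_pet = clim.loc[f"2015-{m:02d}-01", "PET"]
            assert clim.loc[f"2018-{m:02d}-01", "P"] == pytest.approx(
                ref_p * sc.drought_P_multiplier)
            assert clim.loc[f"2018-{m:02d}-01", "PET"] == pytest.approx(
                ref_pet * sc.drought_PET_multiplier)
        # non-drought years untouched
        assert clim.loc["2016-03-01", "P"] == pytest.approx(clim.loc["2015-03-01", "P"])

    def test_mid_year_growing_year_start_shifts_forcing_window(self):
        sc = _quiet(drought_years=(2018,), gy_start_month=10)
        clim = generate_monthly_climate(sc)
        # growing year 2018 with an October start runs Oct 2017 - Sep 2018
        assert clim.loc["2017-10-01", "P"] < clim.loc["2016-10-01", "P"]
        assert clim.loc["2018-10-01", "P"] == pytest.approx(clim.loc["2016-10-01", "P"])

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            generate_monthly_climate(_quiet(n_years=2))


class TestBucket:
    def _random_forcing(self, rng, n=240):
        return rng.uniform(0, 200, n), rng.uniform(20, 250, n)

    def test_storage_bounds_and_exact_closure(self):
        rng = np.random.default_rng(12)
        sc = _quiet()
        P, PET = self._random_forcing(rng)
        out = run_bucket(P, PET, sc)
        assert (out["S"] >= 0).all() and (out["S"] <= sc.S_max).all()
        assert (out["ET"] >= 0).all() and (out["runoff"] >= 0).all()
        S_prev = sc.S_max / 2.0
        for i in range(len(P)):
            lhs = out["S"].iloc[i] - S_prev
            rhs = P[i] - out["ET"].iloc[i] - out["runoff"].iloc[i]
            assert lhs == pytest.approx(rhs, abs=1e-9)
            S_prev = out["S"].iloc[i]

    def test_no_rain_drains_to_zero_et(self):
        sc = _quiet()
        out = run_bucket(np.zeros(120), np.full(120, 150.0), sc)
        assert out["ET"].iloc[-1] == pytest.approx(0.0, abs=1e-6)
        assert out["S"].iloc[-1] == pytest.approx(0.0, abs=1e-6)
        assert (out["runoff"] == 0).all()

    def test_saturated_bucket_spills_and_et_tracks_demand(self):
        sc = _quiet(transport_cap=1.0)
        P = np.full(60, 300.0)
        PET = np.full(60, 50.0)
        out = run_bucket(P, PET, sc)
        # once full: beta = 1, ET = PET, runoff = P - ET
        assert out["ET"].iloc[-1] == pytest.approx(50.0)
        assert out["runoff"].iloc[-1] == pytest.approx(250.0)
        assert out["S"].iloc[-1] == pytest.approx(sc.S_max)

    def test_stress_factor_limits_dry_et(self):
        sc = _quiet()
        # storage held near zero: ET must be far below demand
        out = run_bucket(np.full(60, 5.0), np.full(60, 200.0), sc, S0=0.0)
        assert (out["ET"].iloc[12:] < 0.2 * 200.0).all()


class TestCarbonCoupling:
    def test_uwue_inversion_exact_without_noise_or_cap(self):
        sc = _quiet(light_cap=None)
        et = np.linspace(10, 120, 24)
        vpd = np.linspace(0.5, 2.5, 24)
        out = fluxes_from_water(et, vpd, sc)
        assert np.allclose(out["GPP"] * np.sqrt(vpd) / et, sc.uwue_target)
        assert np.allclose(out["ER"], sc.er_base + sc.er_slope * out["GPP"])
        assert np.allclose(out["NEP"], out["GPP"] - out["ER"])

    def test_light_cap_binds(self):
        sc = _quiet(light_cap=100.0)
        out = fluxes_from_water(np.full(12, 200.0), np.full(12, 1.0), sc)
        assert np.allclose(out["GPP"], 100.0)

    def test_lai_follows_lagged_smoothed_mi(self):
        sc = _quiet(lai_lag=2, lai_gain=0.7)
        et = np.full(60, 50.0)
        P = np.sin(np.linspace(0, 6 * np.pi, 60)) * 40 + 60
        PET = np.full(60, 100.0)
        out = fluxes_from_water(et, np.full(60, 1.0), sc, P=P, PET=PET)
        mi_smooth = pd.Series(P / PET).rolling(3, center=True, min_periods=1).mean()
        expected = sc.lai_base + sc.lai_gain * mi_smooth.shift(2)
        assert np.allclose(out["LAI"][5:], expected[5:])


class TestGenerateSite:
    def test_same_seed_bitwise_reproducible(self):
        a = generate_site(scenario_from_preset("grass", seed=5))
        b = generate_site(scenario_from_preset("grass", seed=5))
        pd.testing.assert_frame_equal(a["monthly"].data, b["monthly"].data)
        c = generate_site(scenario_from_preset("grass", seed=6))
        assert not a["monthly"].data["P"].equals(c["monthly"].data["P"])

    def test_truth_records_imposed_structure(self):
        sc = scenario_from_preset("dry", seed=2, lai_lag=3)
        out = generate_site(sc)
        assert out["truth"]["drought_window"] == (2018, 2019)
        assert out["truth"]["lai_lag"] == 3
        assert out["truth"]["uwue_target"] == sc.uwue_target
        assert len(out["monthly"]) == sc.n_years * 12
        assert "PET" in out["monthly"].data.columns

    def test_grass_declines_more_than_dry_forest(self):
        """Imposed group contrast: grass loses a larger GPP fraction."""
        declines = {}
        for preset in ("grass", "dry"):
            out = generate_site(scenario_from_preset(preset, seed=4))
            monthly = out["monthly"].data
            pre = monthly.loc["2012":"2016", "GPP"].groupby(
                monthly.loc["2012":"2016"].index.year).sum().mean()
            dro = monthly.loc["2018":"2018", "GPP"].sum()
            declines[preset] = (dro - pre) / pre
        assert declines["grass"] < declines["dry"] < 0

    def test_presets_cover_all_groups(self):
        assert set(PRESETS) == {"grass", "very_dry", "dry", "seasonally_wet", "wet"}
        for name in PRESETS:
            sc = scenario_from_preset(name)
            assert isinstance(sc, SiteScenario)
        with pytest.raises(ValueError):
            scenario_from_preset("tundra")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            scenario_from_preset("dry", S_crit=1000.0, S_max=100.0)
        with pytest.raises(ValueError):
            scenario_from_preset("dry", er_slope=1.5)
        with pytest.raises(ValueError):
            scenario_from_preset("dry", drought_P_multiplier=2.0)


class TestDiurnalDisaggregation:
    def _daily(self, sc):
        out = generate_site(sc)
        monthly = out["monthly"].data.loc["2017-06":"2017-07"]
        return monthly_to_daily(monthly)

    def test_totals_conserved_exactly(self):
        sc = scenario_from_preset("dry", seed=1, centroid_shift_drought=1.0)
        daily = self._daily(sc)
        drought_days = daily.index[daily.index >= "2017-07-01"]
        hh = disaggregate_diurnal(daily, sc, drought_dates=drought_days)
        per_day = hh.data.groupby(hh.data.index.floor("D"))[["ET", "GPP"]].sum()
        assert np.allclose(per_day["ET"], daily["ET"], rtol=1e-12)
        assert np.allclose(per_day["GPP"], daily["GPP"], rtol=1e-12)

    def test_zero_shift_keeps_et_and_gpp_proportional(self):
        sc = scenario_from_preset("dry", seed=1, centroid_shift_drought=0.0)
        daily = self._daily(sc)
        hh = disaggregate_diurnal(daily, sc, drought_dates=daily.index).data
        day = hh.loc["2017-06-05"]
        active = day["GPP"] > 0
        ratio = day.loc[active, "ET"] / day.loc[active, "GPP"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_vpd_daily_mean_preserved(self):
        sc = scenario_from_preset("dry", seed=1)
        daily = self._daily(sc)
        hh = disaggregate_diurnal(daily, sc).data
        means = hh.groupby(hh.index.floor("D"))["VPD"].mean()
        assert np.allclose(means, daily["VPD"], rtol=1e-9)


class TestStudyEnsemble:
    def test_fourteen_sites_with_published_rainfall(self):
        scs = ensemble_scenarios(seed=0)
        assert len(scs) == 14
        assert sum(len(c) for _, c in STUDY_GROUP_CLIMATE) == 14
        by_preset = {}
        for sc in scs:
            by_preset.setdefault(sc.preset, []).append(sc.P_mean)
        assert sorted(by_preset["grass"]) == [424.0, 657.0]
        assert len(by_preset["wet"]) == 3

    def test_ensemble_reproducible_per_seed(self):
        a = [s.seed for s in ensemble_scenarios(seed=0)]
        b = [s.seed for s in ensemble_scenarios(seed=0)]
        c = [s.seed for s in ensemble_scenarios(seed=1)]
        assert a == b
        assert a != c


def test_lagged_response_series_recovers_its_lag():
    from fluxdrought import cross_correlation_lag

    drv, resp = lagged_response_series(120, lag=4, noise_sd=0.2, seed=3)
    assert len(drv) == len(resp) == 120
    lc = cross_correlation_lag(drv, resp, max_lag=8)
    assert lc.lag == 4
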