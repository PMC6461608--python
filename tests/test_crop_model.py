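"""Crop simulator, weather QC, calibration, and fit metrics."""

import numpy as np
import pandas as pd
import pytest

from ricegap import (
    CultivarParameters,
    calibrate_partitioning,
    calibrate_phenology,
    fit_metrics,
    gen_phenology_obs,
    qc_weather,
    simulate_crop,
    simulate_potential,
)
from ricegap.crop import (
    PhenologyObservation,
    SeasonTooShortError,
    WeatherQCError,
)
from ricegap.weather import WeatherSeries

from conftest import constant_weather, replicated_weather


class TestWeatherQC:
    def test_clean_series_zero_flags(self, subtropical_weather):
        assert qc_weather(subtropical_weather).n_flagged == 0

    def test_inverted_temperature_flagged_once(self, subtropical_weather):
        df = subtropical_weather.data.copy()
        df.loc[100, ["tmax_C", "tmin_C"]] = [10.0, 20.0]
        bad = WeatherSeries.__new__(WeatherSeries)  # bypass constructor checks
        object.__setattr__(bad, "site_id", "x")
        object.__setattr__(bad, "latitude", subtropical_weather.latitude)
        object.__setattr__(bad, "elevation", 0.0)
        object.__setattr__(bad, "data", df)
        rep = qc_weather(bad)
        assert rep.n_flagged == 1
        assert rep.flags["reason"].tolist() == ["tmax_lt_tmin"]

    def test_radiation_above_envelope_flagged(self, subtropical_weather):
        from ricegap.solar import clear_sky_envelope  # independent envelope
        df = subtropical_weather.data.copy()
        days = [50, 150, 250]
        env = clear_sky_envelope(subtropical_weather.latitude,
                                 df.loc[days, "date"].dt.dayofyear)
        df.loc[days, "srad_MJ_m2"] = 2.0 * env  # twice the clear-sky bound
        bad = WeatherSeries("x", subtropical_weather.latitude, df)
        rep = qc_weather(bad)
        assert rep.n_flagged == 3
        assert (rep.flags["reason"] == "srad_above_envelope").all()

    def test_isolated_gap_imputed(self, subtropical_weather):
        df = subtropical_weather.data.copy()
        cols = ["tmax_C", "tmin_C", "srad_MJ_m2", "rain_mm"]
        df.loc[200, cols] = np.nan
        rep = qc_weather(WeatherSeries("x", subtropical_weather.latitude, df))
        assert rep.n_imputed == 1
        expected = 0.5 * (df.loc[199, "tmax_C"] + df.loc[201, "tmax_C"])
        assert rep.cleaned.data.loc[200, "tmax_C"] == pytest.approx(expected)

    def test_majority_flagged_rejected(self):
        w = constant_weather(100, srad=40.0)  # far above any winter envelope
        with pytest.raises(WeatherQCError):
            qc_weather(w)


class TestSimulateCrop:
    def test_no_radiation_no_yield(self, cultivar):
        w = constant_weather(250, srad=0.0)
        res = simulate_crop(w, cultivar, "2010-01-15")
        assert res.yield_t_ha < 0.1

    def test_yield_increases_with_rue(self, subtropical_weather, cultivar):
        lo = simulate_crop(subtropical_weather, cultivar, "2006-05-10")
        hi = simulate_crop(subtropical_weather,
                           cultivar.replace(rue=2 * cultivar.rue), "2006-05-10")
        assert hi.yield_t_ha > lo.yield_t_ha

    def test_yield_in_observed_potential_range(self, subtropical_weather, cultivar):
        """Simulated potential yields fall in the 8.4-14.4 t/ha band of
        well-managed experimental rice crops."""
        res = simulate_potential(subtropical_weather, cultivar, "05-10")
        assert 8.4 <= res.mean_yield <= 14.4

    def test_mass_balance_and_harvest_index_bound(self, subtropical_weather, cultivar):
        for sow in ("2005-05-10", "2008-05-10", "2012-05-10"):
            res = simulate_crop(subtropical_weather, cultivar, sow)
            assert res.mass_balance_error <= 1e-9
            assert res.yield_t_ha <= cultivar.spikelet_to_yield * res.total_biomass_t_ha + 1e-12

    def test_state_invariants(self, subtropical_weather, cultivar):
        traj = simulate_crop(subtropical_weather, cultivar, "2006-05-10").trajectory
        assert traj["dvs"].is_monotonic_increasing
        assert (traj[["lai", "leaf", "stem", "panicle"]] >= 0).all().all()

    def test_warmer_weather_never_lengthens_phases(self, cultivar):
        """Below topt, added warmth accelerates development."""
        base = constant_weather(250, tmax=27.0, tmin=17.0)
        warm = constant_weather(250, tmax=30.0, tmin=20.0)
        d_base = simulate_crop(base, cultivar, "2010-01-15").duration_days
        d_warm = simulate_crop(warm, cultivar, "2010-01-15").duration_days
        assert d_warm <= d_base

    def test_cool_season_raises(self, cultivar):
        w = constant_weather(250, tmax=12.0, tmin=4.0)
        with pytest.raises(SeasonTooShortError):
            simulate_crop(w, cultivar, "2010-01-15")

    def test_sowing_outside_weather_rejected(self, subtropical_weather, cultivar):
        with pytest.raises(ValueError):
            simulate_crop(subtropical_weather, cultivar, "1999-05-10")


class TestSimulatePotential:
    def test_replicated_weather_zero_cv(self, subtropical_weather, cultivar):
        one_year = subtropical_weather.slice("2006-01-01", "2006-12-31")
        w = replicated_weather(one_year, range(2005, 2015))
        res = simulate_potential(w, cultivar, "05-10")
        assert len(res.seasons) >= 9
        assert res.cv_pct == pytest.approx(0.0, abs=1e-9)

    def test_fixture_cv_in_plausible_band(self, subtropical_weather, cultivar):
        """Interannual potential-yield CV of irrigated rice is small;
        the generator's weather variability should land at a few percent."""
        res = simulate_potential(subtropical_weather, cultivar, "05-10")
        assert 2.0 <= res.cv_pct <= 15.0

    def test_single_year_rejected(self, subtropical_weather, cultivar):
        one = subtropical_weather.slice("2006-01-01", "2006-12-31")
        with pytest.raises(ValueError):
            simulate_potential(one, cultivar, "05-10")

    def test_failed_years_reported_not_dropped(self, subtropical_weather, cultivar):
        # a cultivar so slow it cannot mature within the season limit
        slow = cultivar.replace(dvrr=cultivar.dvrr / 20.0)
        with pytest.raises(ValueError, match="failed"):
            simulate_potential(subtropical_weather, slow, "05-10")


class TestCalibratePhenology:
    def _observations(self, weather, truth, years, noise, seeds):
        obs = []
        for seed, year in zip(seeds, years):
            sd, _ = gen_phenology_obs(truth, weather, f"{year}-05-10",
                                      noise_sd_days=noise, seed=seed)
            obs.append(PhenologyObservation(weather, pd.Timestamp(f"{year}-05-10"), sd))
        return obs

    def test_zero_noise_exact_recovery(self, subtropical_weather):
        truth = CultivarParameters(dvrj=0.00085, dvri=0.00070,
                                   dvrp=0.00060, dvrr=0.00180)
        obs = self._observations(subtropical_weather, truth,
                                 (2005, 2006), 0.0, (1, 2))
        cal = calibrate_phenology(obs, CultivarParameters())
        for attr in ("dvrj", "dvri", "dvrp", "dvrr"):
            assert getattr(cal, attr) == pytest.approx(getattr(truth, attr), rel=1e-3)

    def test_contradictory_duplicates_compromise(self, subtropical_weather, cultivar):
        """Two conflicting observations of the same season yield a
        least-squares compromise without crashing."""
        sd, _ = gen_phenology_obs(cultivar, subtropical_weather, "2006-05-10", seed=0)
        shifted = {k: (v + 4.0 if k != "emergence" else v) for k, v in sd.items()}
        obs = [
            PhenologyObservation(subtropical_weather, pd.Timestamp("2006-05-10"), sd),
            PhenologyObservation(subtropical_weather, pd.Timestamp("2006-05-10"), shifted),
        ]
        cal = calibrate_phenology(obs, cultivar)
        for attr in ("dvrj", "dvri", "dvrp", "dvrr"):
            assert 0 < getattr(cal, attr) < 1

    def test_unreachable_stage_rejected(self, subtropical_weather, cultivar):
        sd, _ = gen_phenology_obs(cultivar, subtropical_weather, "2006-05-10", seed=0)
        sd = dict(sd)
        sd["juvenile_end"] = sd["emergence"]  # zero-duration phase
        obs = [PhenologyObservation(subtropical_weather, pd.Timestamp("2006-05-10"), sd)]
        with pytest.raises(ValueError):
            calibrate_phenology(obs, cultivar)


class TestCalibratePartitioning:
    def test_zero_noise_exact_recovery(self, subtropical_weather):
        truth = CultivarParameters(sla=0.017)
        _, samples = gen_phenology_obs(truth, subtropical_weather, "2006-05-10", seed=0)
        cal = calibrate_partitioning(samples, CultivarParameters())
        assert cal.sla == pytest.approx(truth.sla, rel=1e-9)
        for got, want in zip(cal.partition_table.leaf, truth.partition_table.leaf):
            assert got == pytest.approx(want, abs=1e-9)
        for got, want in zip(cal.partition_table.panicle, truth.partition_table.panicle):
            assert got == pytest.approx(want, abs=1e-9)

    def test_fractions_valid_under_noise(self, subtropical_weather, cultivar):
        _, samples = gen_phenology_obs(cultivar, subtropical_weather, "2006-05-10",
                                       biomass_noise_cv=0.08, seed=3)
        table = calibrate_partitioning(samples, cultivar).partition_table
        for i in range(len(table.leaf)):
            assert table.leaf[i] + table.stem[i] + table.panicle[i] == pytest.approx(1.0)

    def test_two_point_series_rejected(self, cultivar):
        samples = pd.DataFrame({"day": [0, 100], "dvs": [0.0, 2.0],
                                "leaf": [0.1, 2.0], "stem": [0.0, 6.0],
                                "panicle": [0.0, 8.0], "lai": [0.1, 2.0]})
        with pytest.raises(ValueError):
            calibrate_partitioning(samples, cultivar)

    def test_non_monotonic_dvs_rejected(self, cultivar):
        samples = pd.DataFrame({"day": [0, 40, 80], "dvs": [0.0, 1.2, 1.0],
                                "leaf": [0.1, 1.0, 2.0], "stem": [0.0, 2.0, 6.0],
                                "panicle": [0.0, 1.0, 8.0], "lai": [0.1, 2.0, 2.0]})
        with pytest.raises(ValueError):
            calibrate_partitioning(samples, cultivar)


class TestRoundTrip:
    def test_forward_calibrate_forward_yield_within_1pct(self, subtropical_weather):
        truth = CultivarParameters(dvrj=0.0008, dvri=0.0007, dvrp=0.00058,
                                   dvrr=0.0019, sla=0.016)
        obs, samples = [], None
        for seed, year in zip((1, 2), (2005, 2006)):
            sd, samples = gen_phenology_obs(truth, subtropical_weather,
                                            f"{year}-05-10", seed=seed)
            obs.append(PhenologyObservation(subtropical_weather,
                                            pd.Timestamp(f"{year}-05-10"), sd))
        cal = calibrate_phenology(obs, CultivarParameters())
        cal = calibrate_partitioning(samples, cal)
        y_true = simulate_crop(subtropical_weather, truth, "2007-05-10").yield_t_ha
        y_cal = simulate_crop(subtropical_weather, cal, "2007-05-10").yield_t_ha
        assert y_cal == pytest.approx(y_true, rel=0.01)


class TestFitMetrics:
    def test_perfect_agreement(self):
        m = fit_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0
        assert m.rmse_n == 0.0

    def test_proportional_vectors(self):
        m = fit_metrics([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(14.0 / 3.0))
        assert m.rmse_n == pytest.approx(np.sqrt(14.0 / 3.0) / 2.0 * 100.0)

    def test_nine_pct_normalized_rmse(self):
        # rmse 0.9 against an observed mean of 10 reads as 9%
        m = fit_metrics([9.9, 11.9], [9.0, 11.0])
        assert m.rmse == pytest.approx(0.9)
        assert m.rmse_n == pytest.approx(9.0)

    def test_zero_variance_r2_undefined(self):
        with pytest.warns(RuntimeWarning):
            m = fit_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(m.r2)
        assert m.rmse > 0

    def test_matches_two_pass_oracle(self):
        """Random vectors against a naive independent implementation."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(2, 40)
            x = rng.normal(5, 2, n)
            y = rng.normal(5, 2, n)
            m = fit_metrics(x, y)
            r = np.corrcoef(x, y)[0, 1] ** 2
            rmse = np.sqrt(np.mean((x - y) ** 2))
            assert m.r2 == pytest.approx(r, abs=1e-10)
            assert m.rmse == pytest.approx(rmse, abs=1e-10)
            assert m.rmse_n == pytest.approx(rmse / np.mean(y) * 100, abs=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_metrics([1.0, 2.0], [1.0, 2.0, 3.0])
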