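"""Generator behavior: determinism, seasonality, missingness, mortality noise."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airmort import synthetic
from airmort.synthetic import (
    COVARIATES,
    GroundTruthModel,
    SimulationConfig,
    generate_hourly_station_data,
    generate_mortality,
    inject_block_outages,
    inject_missingness,
)


def _noiseless_config(**overrides) -> SimulationConfig:
    defaults = dict(
        start_date="2007-01-01",
        end_date="2007-03-31",
        n_stations_per_pollutant=1,
        seasonal_amplitude={c: 0.0 for c in COVARIATES},
        missing_rate=0.0,
        ar1_sd_frac=0.0,
        lognoise_sigma=0.0,
        station_factor_spread=0.0,
        seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_reversed_date_range_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            SimulationConfig(start_date="2010-01-01", end_date="2009-01-01")

    def test_nonpositive_base_level_rejected(self):
        levels = synthetic._default_base_levels()
        levels["pm10"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(base_levels=levels)

    def test_effect_weights_must_sum_to_one(self):
        weights = {c: 0.5 for c in COVARIATES}
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(effect_weights=weights)

    def test_missing_rate_bounds(self):
        with pytest.raises(ValueError, match="missing_rate"):
            SimulationConfig(missing_rate=1.0)


class TestHourlyGeneration:
    def test_noiseless_flat_series_equals_base_level(self):
        cfg = _noiseless_config()
        for series in generate_hourly_station_data(cfg):
            np.testing.assert_allclose(series.values, cfg.base_levels[series.pollutant])

    def test_seeded_determinism(self, small_config):
        a = generate_hourly_station_data(small_config)
        b = generate_hourly_station_data(small_config)
        for sa, sb in zip(a, b):
            assert sa.station_id == sb.station_id
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_dry_season_mean_exceeds_rainy_season_mean(self):
        # 10 simulated years; oracle = direct averaging of the emitted series
        cfg = SimulationConfig(
            start_date="2007-01-01",
            end_date="2016-12-31",
            n_stations_per_pollutant=1,
            seasonal_amplitude={**synthetic._default_seasonal_amplitude(), "pm10": 0.3},
            missing_rate=0.0,
            seed=7,
        )
        for series in generate_hourly_station_data(cfg):
            months = series.timestamps.month
            dry = series.values[np.isin(months, range(4, 10))]
            rainy = series.values[~np.isin(months, range(4, 10))]
            assert np.nanmean(dry) / np.nanmean(rainy) > 1.0

    def test_values_nonnegative_and_hourly_grid(self, scenario):
        for series in scenario.hourly:
            present = series.values[~np.isnan(series.values)]
            assert (present >= 0).all()
            deltas = np.diff(series.timestamps.asi8)
            assert (deltas == 3_600_000_000_000).all()


class TestMissingness:
    def _series(self, n_hours=10_000):
        idx = pd.date_range("2007-01-01", periods=n_hours, freq="h")
        return synthetic.HourlyStationSeries("S1", "pm10", idx, np.full(n_hours, 10.0))

    def test_rate_zero_is_identity(self):
        s = self._series(100)
        out = inject_missingness(s, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, s.values)

    def test_masked_fraction_within_binomial_band(self):
        out = inject_missingness(self._series(), 0.5, seed=2)
        frac = np.isnan(out.values).mean()
        assert 0.47 <= frac <= 0.53  # 99% binomial interval at n=10,000

    def test_remasking_at_zero_preserves_existing_gaps(self):
        masked = inject_missingness(self._series(), 0.3, seed=3)
        again = inject_missingness(masked, 0.0, seed=4)
        np.testing.assert_array_equal(again.values, masked.values)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_missingness(self._series(100), 1.0, seed=1)

    def test_block_outages_mask_contiguous_hours(self):
        out = inject_block_outages(self._series(1000), n_outages=2, outage_hours=24, seed=5)
        n_missing = int(np.isnan(out.values).sum())
        assert 24 <= n_missing <= 48  # blocks may overlap


class TestMortality:
    def _covariates(self, n_days: int, seed: int = 0, start="2007-01-01") -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        dates = pd.date_range(start, periods=n_days, freq="D")
        out = {"date": dates}
        for c in COVARIATES:
            out[c] = rng.normal(50.0, 10.0, size=n_days)
        return pd.DataFrame(out)

    def test_poisson_limit_mean_count(self):
        # no covariate effect, no seasonality, baseline 5/10^5, pop 2M -> 100/day
        years = {y: 2_000_000 for y in range(2007, 2040)}
        cfg = SimulationConfig(
            end_date="2039-12-31",
            noise_dispersion=np.inf,
            elderly_population_by_year=years,
            seed=11,
        )
        truth = GroundTruthModel(
            effect_weights=synthetic._default_effect_weights(),
            baseline_rate=5.0,
            seasonal_mortality_amplitude=0.0,
            effect_scale=0.0,
        )
        cov = self._covariates(10_000)
        sim = generate_mortality(cov, truth, cfg)
        assert 98.0 <= sim.frame["deaths"].mean() <= 102.0

    def test_single_active_covariate_drives_rate(self):
        weights = {c: 0.0 for c in COVARIATES}
        weights["pm10"] = 1.0
        years = {y: 2_000_000 for y in range(2007, 2020)}
        cfg = SimulationConfig(elderly_population_by_year=years, seed=12)
        truth = GroundTruthModel(
            effect_weights=weights, baseline_rate=5.0, seasonal_mortality_amplitude=0.0,
            effect_scale=0.3,
        )
        cov = self._covariates(2000, seed=3)
        sim = generate_mortality(cov, truth, cfg)
        rate = sim.frame["deaths"] / sim.frame["elderly_population"] * 1e5
        rho = stats.spearmanr(cov["pm10"], np.log(rate + 1e-9)).statistic
        assert rho > 0.2

    def test_zero_population_rejected(self):
        cfg = SimulationConfig(elderly_population_by_year={2007: 0}, seed=1)
        truth = GroundTruthModel(
            effect_weights=synthetic._default_effect_weights(),
            baseline_rate=5.0,
            seasonal_mortality_amplitude=0.0,
        )
        with pytest.raises(ValueError, match="population"):
            generate_mortality(self._covariates(10), truth, cfg)

    def test_missing_covariates_rejected(self):
        cfg = SimulationConfig(seed=1)
        truth = GroundTruthModel(
            effect_weights=synthetic._default_effect_weights(),
            baseline_rate=5.0,
            seasonal_mortality_amplitude=0.0,
        )
        cov = self._covariates(10)
        cov.loc[3, "no2"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            generate_mortality(cov, truth, cfg)

    def test_standardization_recorded_on_truth(self, scenario):
        assert scenario.truth.covariate_means is not None
        for c in COVARIATES:
            assert np.isfinite(scenario.truth.covariate_means[c])
            assert scenario.truth.covariate_sds[c] > 0


class TestScenario:
    def test_seeded_scenario_bit_reproducible(self, small_config, scenario):
        again = synthetic.simulate_scenario(small_config)
        pd.testing.assert_frame_equal(again.mortality, scenario.mortality)
        pd.testing.assert_frame_equal(again.meteorology, scenario.meteorology)

    def test_default_rate_range_plausible_across_seeds(self):
        # study-scale order of magnitude: daily rates stay within 1-12 per 10^5
        for seed in range(10):
            sc = synthetic.simulate_scenario(SimulationConfig(seed=seed))
            rates = sc.mortality["deaths"] / sc.mortality["elderly_population"] * 1e5
            assert rates.min() >= 1.0 and rates.max() <= 12.0

    def test_csv_round_trip(self, scenario, tmp_path):
        from airmort import preprocess

        paths = scenario.write_csvs(tmp_path)
        hourly = preprocess.load_hourly_csv(paths["hourly"])
        assert len(hourly) == len(scenario.hourly)
        met = preprocess.load_meteorology_csv(paths["meteorology"])
        assert list(met.columns) == ["date", "temperature", "relative_humidity", "wind_speed"]
        mort = preprocess.load_mortality_csv(paths["mortality"])
        assert mort["deaths"].equals(scenario.mortality["deaths"])
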