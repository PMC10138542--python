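"""Synthetic multi-station pollution / meteorology / mortality scenarios.

Emulates the statistical structure of the São Paulo study inputs so the
whole modelling pipeline is testable without access to the real monitoring
portals: hourly station-level pollutant concentrations with missingness,
daily meteorology, and daily elderly cardiorespiratory death counts driven
by a known ground-truth exposure-response model.

Seasonal convention (southern-hemisphere subtropics): the *dry* season runs
April-September and carries the pollutant and mortality peaks; the *rainy*
season (October-March) carries the temperature and humidity peaks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

POLLUTANTS = ("pm10", "no2", "so2")
MET_VARIABLES = ("temperature", "relative_humidity", "wind_speed")
COVARIATES = POLLUTANTS + MET_VARIABLES

#: day-of-year of the mid-dry-season (≈ July 15) / mid-rainy-season (≈ Jan 15) peaks
_DRY_PEAK_DOY = 196.0
_RAINY_PEAK_DOY = 15.0

# variables whose seasonal maximum falls in the rainy season
_RAINY_PEAKED = {"temperature", "relative_humidity"}


def _default_base_levels() -> dict[str, float]:
    # pollutant annual means sit inside the study's reported 2007-2019 ranges
    # (PM10 28-42, NO2 40-58, SO2 1.7-9.7 µg/m³); meteorology is São Paulo-like.
    return {
        "pm10": 35.0,       # µg/m³
        "no2": 48.0,        # µg/m³
        "so2": 5.0,         # µg/m³
        "temperature": 19.0,        # °C
        "relative_humidity": 78.0,  # %
        "wind_speed": 2.4,          # m/s
    }


def _default_seasonal_amplitude() -> dict[str, float]:
    return {
        "pm10": 0.30,
        "no2": 0.25,
        "so2": 0.25,
        "temperature": 0.20,
        "relative_humidity": 0.05,
        "wind_speed": 0.08,
    }


def _default_effect_weights() -> dict[str, float]:
    return {
        "pm10": 0.25,
        "no2": 0.20,
        "so2": 0.15,
        "temperature": 0.15,
        "relative_humidity": 0.15,
        "wind_speed": 0.10,
    }


def _default_population() -> dict[int, int]:
    # linear growth 1.2M -> 1.9M across 2007-2019, the study city's elderly trend
    years = range(2007, 2020)
    return {y: int(round(1_200_000 + (1_900_000 - 1_200_000) * (y - 2007) / 12)) for y in years}


@dataclass
class SimulationConfig:
    """Scenario definition for one synthetic study period.

    ``seasonal_amplitude`` entries are fractional (0.3 = ±30% around the
    annual mean).  ``effect_weights`` are the ground-truth relative
    importances of the six covariates on log mortality rate; they must be
    nonnegative and sum to 1.  ``noise_dispersion`` is the negative-binomial
    shape of the daily death counts (np.inf = Poisson).
    """

    start_date: str = "2007-01-01"
    end_date: str = "2010-12-31"
    n_stations_per_pollutant: int = 3
    seasonal_amplitude: dict[str, float] = field(default_factory=_default_seasonal_amplitude)
    base_levels: dict[str, float] = field(default_factory=_default_base_levels)
    missing_rate: float = 0.10
    effect_weights: dict[str, float] = field(default_factory=_default_effect_weights)
    noise_dispersion: float = 50.0
    elderly_population_by_year: dict[int, int] = field(default_factory=_default_population)
    seed: int = 0
    # noise structure of the hourly signal (set the sigmas to 0 for noiseless runs)
    ar1_coef: float = 0.8
    ar1_sd_frac: float = 0.10
    lognoise_sigma: float = 0.15
    station_factor_spread: float = 0.10
    baseline_rate: float = 4.5          # deaths per 10^5 elderly per day
    seasonal_mortality_amplitude: float = 0.20
    effect_scale: float = 0.20          # log-rate units per SD of the weighted composite
    # optional season-specific weights {'rainy': {...}, 'dry': {...}} overriding
    # effect_weights day by day (models a covariate-response relation that
    # changes with season, the stratified-modelling use case)
    effect_weights_by_season: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        start = pd.Timestamp(self.start_date)
        end = pd.Timestamp(self.end_date)
        if end < start:
            raise ValueError(f"end_date {self.end_date} precedes start_date {self.start_date}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        for name, level in self.base_levels.items():
            if level <= 0:
                raise ValueError(f"base level for {name} must be positive, got {level}")
        weight_sets = [self.effect_weights]
        if self.effect_weights_by_season is not None:
            if set(self.effect_weights_by_season) != {"rainy", "dry"}:
                raise ValueError("effect_weights_by_season needs exactly the keys rainy and dry")
            weight_sets += list(self.effect_weights_by_season.values())
        for ws in weight_sets:
            w = np.array([ws[c] for c in COVARIATES], dtype=float)
            if (w < 0).any():
                raise ValueError("effect_weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"effect_weights must sum to 1, got {w.sum()!r}")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")


@dataclass
class HourlyStationSeries:
    """One station's hourly concentration record for one pollutant.

    ``values`` holds concentrations in µg/m³ with NaN marking missing hours;
    ``timestamps`` is a strictly increasing hourly grid.
    """

    station_id: str
    pollutant: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values length mismatch")
        present = self.values[~np.isnan(self.values)]
        if (present < 0).any():
            raise ValueError("concentrations must be nonnegative where present")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "pollutant": self.pollutant,
                "timestamp": self.timestamps,
                "value": self.values,
            }
        )


@dataclass
class GroundTruthModel:
    """The exposure-response model that generated a synthetic scenario.

    log(rate_t) = log(baseline_rate)
                  + effect_scale * Σ_i w_i z_it
                  + seasonal_mortality_amplitude * cos(2π (doy_t − dry peak)/365.25)

    with z the covariates standardized by the long-run means/SDs recorded in
    ``covariate_means`` / ``covariate_sds`` after generation.
    """

    effect_weights: dict[str, float]
    baseline_rate: float
    seasonal_mortality_amplitude: float
    effect_scale: float = 0.20
    link: str = "log"
    effect_weights_by_season: dict[str, dict[str, float]] | None = None
    covariate_means: dict[str, float] | None = None
    covariate_sds: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        w = np.array(list(self.effect_weights.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("effect_weights must sum to 1")


def _seasonal_factor(doy: np.ndarray, amplitude: float, variable: str) -> np.ndarray:
    peak = _RAINY_PEAK_DOY if variable in _RAINY_PEAKED else _DRY_PEAK_DOY
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (doy - peak) / 365.25)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _hourly_grid(config: SimulationConfig) -> pd.DatetimeIndex:
    return pd.date_range(
        config.start_date, pd.Timestamp(config.end_date) + pd.Timedelta(hours=23), freq="h"
    )


def _citywide_hourly_signal(config: SimulationConfig, pollutant: str, p_i: int) -> np.ndarray:
    """Shared citywide signal: seasonal sinusoid + stationary AR(1) deviations."""
    idx = _hourly_grid(config)
    doy = idx.dayofyear.to_numpy(dtype=float)
    base = config.base_levels[pollutant]
    amp = config.seasonal_amplitude.get(pollutant, 0.0)
    season = base * _seasonal_factor(doy, amp, pollutant)
    ar = np.zeros(len(idx))
    if config.ar1_sd_frac > 0:
        innov_sd = base * config.ar1_sd_frac * np.sqrt(1.0 - config.ar1_coef**2)
        eps = _rng(config.seed, 1, p_i).normal(0.0, innov_sd, size=len(idx))
        ar[0] = eps[0] / np.sqrt(1.0 - config.ar1_coef**2)
        for t in range(1, len(idx)):
            ar[t] = config.ar1_coef * ar[t - 1] + eps[t]
    return season + ar


def generate_hourly_station_data(config: SimulationConfig) -> list[HourlyStationSeries]:
    """Generate one hourly series per station per pollutant.

    The citywide signal is a one-year-period sinusoid (maxima mid dry
    season) plus AR(1) deviations; each station observes it through a fixed
    multiplicative station factor and hour-level lognormal noise, truncated
    at zero.  Deterministic given ``config.seed``; missingness is applied
    afterwards via :func:`inject_missingness`.
    """
    idx = _hourly_grid(config)
    out: list[HourlyStationSeries] = []
    for p_i, pollutant in enumerate(POLLUTANTS):
        citywide = _citywide_hourly_signal(config, pollutant, p_i)
        for s_i in range(config.n_stations_per_pollutant):
            st_rng = _rng(config.seed, 2, p_i, s_i)
            factor = 1.0
            if config.station_factor_spread > 0:
                factor = float(np.exp(st_rng.normal(0.0, config.station_factor_spread)))
            noise = 1.0
            if config.lognoise_sigma > 0:
                noise = np.exp(st_rng.normal(0.0, config.lognoise_sigma, size=len(idx)))
            values = np.maximum(citywide * factor * noise, 0.0)
            series = HourlyStationSeries(
                station_id=f"{pollutant.upper()}_S{s_i + 1}",
                pollutant=pollutant,
                timestamps=idx,
                values=values,
            )
            if config.missing_rate > 0:
                series = inject_missingness(series, config.missing_rate, seed=int(_rng(config.seed, 3, p_i, s_i).integers(2**31)))
            out.append(series)
    return out


def inject_missingness(series: HourlyStationSeries, missing_rate: float, seed: int) -> HourlyStationSeries:
    """Mask each hourly value independently with probability ``missing_rate`` (MCAR)."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    values = series.values.copy()
    if missing_rate > 0:
        mask = np.random.default_rng(seed).random(len(values)) < missing_rate
        values[mask] = np.nan
    return HourlyStationSeries(series.station_id, series.pollutant, series.timestamps, values)


def inject_block_outages(
    series: HourlyStationSeries, n_outages: int, outage_hours: int, seed: int
) -> HourlyStationSeries:
    """Mask ``n_outages`` contiguous blocks of ``outage_hours`` hours.

    Real monitoring gaps are bursty (instrument downtime), not independent
    per hour; this mode complements the MCAR default.
    """
    if n_outages < 0 or outage_hours <= 0:
        raise ValueError("n_outages must be >= 0 and outage_hours positive")
    values = series.values.copy()
    rng = np.random.default_rng(seed)
    n = len(values)
    for _ in range(n_outages):
        start = int(rng.integers(0, max(n - outage_hours, 1)))
        values[start : start + outage_hours] = np.nan
    return HourlyStationSeries(series.station_id, series.pollutant, series.timestamps, values)


def generate_meteorology(config: SimulationConfig) -> pd.DataFrame:
    """Daily mean temperature (°C), relative humidity (%), wind speed (m/s).

    Temperature and humidity peak in the rainy (summer) season; humidity is
    clipped to [0, 100] and wind to >= 0.
    """
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    out = {"date": dates}
    for m_i, var in enumerate(MET_VARIABLES):
        base = config.base_levels[var]
        amp = config.seasonal_amplitude.get(var, 0.0)
        season = base * _seasonal_factor(doy, amp, var)
        rng = _rng(config.seed, 4, m_i)
        dev = np.zeros(len(dates))
        if config.ar1_sd_frac > 0:
            innov_sd = base * config.ar1_sd_frac * np.sqrt(1.0 - config.ar1_coef**2)
            eps = rng.normal(0.0, innov_sd, size=len(dates))
            for t in range(1, len(dates)):
                dev[t] = config.ar1_coef * dev[t - 1] + eps[t]
        vals = season + dev
        if var == "relative_humidity":
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.maximum(vals, 0.0)
        out[var] = vals
    return pd.DataFrame(out)


@dataclass
class MortalitySimulation:
    """Daily death counts plus the ground truth that produced them."""

    frame: pd.DataFrame            # date, deaths, elderly_population
    truth: GroundTruthModel
    expected_rate: np.ndarray      # deaths per 10^5 elderly per day


def generate_mortality(
    daily_covariates: pd.DataFrame,
    truth: GroundTruthModel,
    config: SimulationConfig,
) -> MortalitySimulation:
    """Draw daily elderly death counts from the ground-truth rate model.

    ``daily_covariates`` must contain a ``date`` column and complete values
    for all six covariates.  Counts are negative binomial with shape
    ``config.noise_dispersion`` around expected_rate × population / 10⁵
    (``np.inf`` gives the Poisson limit).  Standardization means/SDs are
    computed from the supplied covariates and recorded on the returned
    truth model so recovery tests are exact.
    """
    cov = daily_covariates.reset_index(drop=True)
    missing_cols = [c for c in COVARIATES if c not in cov.columns]
    if missing_cols:
        raise ValueError(f"daily covariates missing columns: {missing_cols}")
    if cov[list(COVARIATES)].isna().any().any():
        raise ValueError("daily covariates contain missing values")

    dates = pd.DatetimeIndex(cov["date"])
    years = dates.year
    pop = np.array([config.elderly_population_by_year.get(int(y), 0) for y in years], dtype=float)
    if (pop <= 0).any():
        bad = sorted(set(int(y) for y, p in zip(years, pop) if p <= 0))
        raise ValueError(f"nonpositive elderly population for years {bad}")

    means = {c: float(cov[c].mean()) for c in COVARIATES}
    sds = {c: float(cov[c].std(ddof=0)) or 1.0 for c in COVARIATES}
    truth = dataclasses.replace(truth, covariate_means=means, covariate_sds=sds)

    z = np.column_stack([(cov[c].to_numpy() - means[c]) / sds[c] for c in COVARIATES])
    if truth.effect_weights_by_season is not None:
        dry = np.isin(dates.month, range(4, 10))
        w_dry = np.array([truth.effect_weights_by_season["dry"][c] for c in COVARIATES])
        w_rainy = np.array([truth.effect_weights_by_season["rainy"][c] for c in COVARIATES])
        composite = np.where(dry, z @ w_dry, z @ w_rainy)
    else:
        w = np.array([truth.effect_weights[c] for c in COVARIATES])
        composite = z @ w
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = truth.seasonal_mortality_amplitude * np.cos(2.0 * np.pi * (doy - _DRY_PEAK_DOY) / 365.25)
    log_rate = np.log(truth.baseline_rate) + truth.effect_scale * composite + seasonal
    rate = np.exp(log_rate)
    mean_counts = rate * pop / 1e5

    rng = _rng(config.seed, 5)
    if np.isinf(config.noise_dispersion):
        deaths = rng.poisson(mean_counts)
    else:
        k = config.noise_dispersion
        lam = rng.gamma(shape=k, scale=mean_counts / k)
        deaths = rng.poisson(lam)
    frame = pd.DataFrame(
        {"date": dates, "deaths": deaths.astype(int), "elderly_population": pop.astype(int)}
    )
    return MortalitySimulation(frame=frame, truth=truth, expected_rate=rate)


@dataclass
class SyntheticScenario:
    """Everything one simulated study period produced."""

    config: SimulationConfig
    hourly: list[HourlyStationSeries]
    meteorology: pd.DataFrame
    mortality: pd.DataFrame
    truth: GroundTruthModel
    expected_rate: np.ndarray

    def write_csvs(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three study input files (long hourly CSV, daily meteorology, mortality)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "hourly": out / "hourly_pollutants.csv",
            "meteorology": out / "daily_meteorology.csv",
            "mortality": out / "daily_mortality.csv",
        }
        hourly = pd.concat([s.to_frame() for s in self.hourly], ignore_index=True)
        hourly["timestamp"] = hourly["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        hourly.to_csv(paths["hourly"], index=False)
        met = self.meteorology.copy()
        met.columns = ["date", "temperature_c", "relative_humidity_pct", "wind_speed_ms"]
        met["date"] = pd.DatetimeIndex(met["date"]).strftime("%Y-%m-%d")
        met.to_csv(paths["meteorology"], index=False)
        mort = self.mortality.copy()
        mort["date"] = pd.DatetimeIndex(mort["date"]).strftime("%Y-%m-%d")
        mort.to_csv(paths["mortality"], index=False)
        return paths


def simulate_scenario(config: SimulationConfig) -> SyntheticScenario:
    """Run the full generator: hourly pollutants, meteorology, mortality.

    Mortality is driven by the *citywide daily truth covariates* (the
    noise-free station-mean daily pollutant signal plus the emitted daily
    meteorology), so the ground-truth covariate-response relation is exact
    at the daily scale even though the hourly station data carry noise and
    gaps.
    """
    hourly = generate_hourly_station_data(config)
    met = generate_meteorology(config)

    # daily citywide pollutant exposure underlying the mortality draw:
    # station-mean of the noiseless daily signal == seasonal + AR(1) daily mean
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    cov = {"date": dates}
    idx = _hourly_grid(config)
    for p_i, pollutant in enumerate(POLLUTANTS):
        citywide = np.maximum(_citywide_hourly_signal(config, pollutant, p_i), 0.0)
        daily = pd.Series(citywide, index=idx).resample("D").mean()
        cov[pollutant] = daily.to_numpy()
    for var in MET_VARIABLES:
        cov[var] = met[var].to_numpy()
    cov_df = pd.DataFrame(cov)

    truth = GroundTruthModel(
        effect_weights=dict(config.effect_weights),
        baseline_rate=config.baseline_rate,
        seasonal_mortality_amplitude=config.seasonal_mortality_amplitude,
        effect_scale=config.effect_scale,
        effect_weights_by_season=config.effect_weights_by_season,
    )
    sim = generate_mortality(cov_df, truth, config)
    return SyntheticScenario(
        config=config,
        hourly=hourly,
        meteorology=met,
        mortality=sim.frame,
        truth=sim.truth,
        expected_rate=sim.expected_rate,
    )
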