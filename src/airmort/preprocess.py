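"""Daily modeling table construction.

Turns hourly station pollutant records, daily meteorology, and daily death
counts into the aligned complete-case table the models consume:

* daily station means only for days with strictly more than 75% of hourly
  values present (> 18 of 24 hours),
* citywide pollutant concentration = unweighted mean over the eligible
  stations reporting that day,
* mortality relativized to deaths per 10^5 elderly using the year's
  population,
* season labels (rainy = October-March, dry = April-September),
* min-max scaling of the covariates to [-1, 1] for the neural networks,
  computed on the full dataset and stored so predictions return to the
  original scale.  The GLM consumes the unscaled covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import COVARIATES, HourlyStationSeries

RAINY_MONTHS = frozenset({10, 11, 12, 1, 2, 3})
DRY_MONTHS = frozenset({4, 5, 6, 7, 8, 9})

#: strictly more than 75% of 24 hourly slots must be present
MIN_HOURS_PRESENT = 18


def daily_mean_with_completeness(hourly_values: Sequence[float], min_present: int = MIN_HOURS_PRESENT) -> float:
    """Mean of one day's 24 hourly slots, or NaN if too few are present.

    A day qualifies only when strictly more than ``min_present`` of its 24
    hours carry data (default: > 18, i.e. more than 75%).
    """
    values = np.asarray(hourly_values, dtype=float)
    if values.shape != (24,):
        raise ValueError(f"expected exactly 24 hourly slots, got shape {values.shape}")
    present = ~np.isnan(values)
    if present.sum() <= min_present:
        return float("nan")
    return float(values[present].mean())


def station_daily_means(series: HourlyStationSeries, min_present: int = MIN_HOURS_PRESENT) -> pd.Series:
    """Apply the completeness rule day by day to one station's hourly record."""
    s = pd.Series(series.values, index=series.timestamps)
    grouped = s.groupby(s.index.normalize())
    counts = grouped.count()
    means = grouped.mean()
    means[counts <= min_present] = np.nan
    means.name = series.station_id
    return means


def citywide_daily_mean(station_daily: pd.DataFrame, eligible_stations: Iterable[str]) -> pd.Series:
    """Unweighted mean over the eligible stations reporting each day.

    ``station_daily`` has one column per station (daily values, NaN =
    missing).  Days where every eligible station is missing stay NaN.
    """
    eligible = list(eligible_stations)
    if not eligible:
        raise ValueError("eligible station set must be nonempty")
    missing = [s for s in eligible if s not in station_daily.columns]
    if missing:
        raise ValueError(f"eligible stations absent from data: {missing}")
    return station_daily[eligible].mean(axis=1, skipna=True)


def pollutant_daily_table(
    hourly: Iterable[HourlyStationSeries], min_present: int = MIN_HOURS_PRESENT
) -> pd.DataFrame:
    """Citywide daily mean per pollutant from a collection of station series.

    Every supplied station is treated as eligible (the study's station
    screening — keep only stations covering the whole series — happens at
    collection time; synthetic stations always qualify).
    """
    by_pollutant: dict[str, list[pd.Series]] = {}
    for series in hourly:
        by_pollutant.setdefault(series.pollutant, []).append(station_daily_means(series, min_present))
    cols = {}
    for pollutant, dailies in by_pollutant.items():
        table = pd.concat(dailies, axis=1)
        cols[pollutant] = citywide_daily_mean(table, table.columns)
    out = pd.DataFrame(cols)
    out.index.name = "date"
    return out.reset_index()


def compute_mortality_rate(deaths: float, elderly_population: float) -> float:
    """Deaths per 10^5 elderly inhabitants."""
    if elderly_population <= 0:
        raise ValueError(f"elderly population must be positive, got {elderly_population}")
    if deaths < 0:
        raise ValueError("death count cannot be negative")
    return deaths / elderly_population * 1e5


def assign_season(date) -> str:
    """'rainy' for October-March, 'dry' for April-September."""
    month = pd.Timestamp(date).month
    return "rainy" if month in RAINY_MONTHS else "dry"


@dataclass
class MinMaxScaling:
    """Per-column (min, max) mapping the data range onto [-1, 1]."""

    minima: dict[str, float]
    maxima: dict[str, float]

    @classmethod
    def fit(cls, frame: pd.DataFrame, columns: Sequence[str]) -> "MinMaxScaling":
        return cls(
            minima={c: float(frame[c].min()) for c in columns},
            maxima={c: float(frame[c].max()) for c in columns},
        )

    def scale(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for c, lo in self.minima.items():
            hi = self.maxima[c]
            span = hi - lo
            out[c] = 0.0 if span == 0 else 2.0 * (frame[c] - lo) / span - 1.0
        return out

    def scale_column(self, values: np.ndarray, column: str) -> np.ndarray:
        lo, hi = self.minima[column], self.maxima[column]
        span = hi - lo
        if span == 0:
            return np.zeros_like(np.asarray(values, dtype=float))
        return 2.0 * (np.asarray(values, dtype=float) - lo) / span - 1.0

    def unscale_column(self, values: np.ndarray, column: str) -> np.ndarray:
        lo, hi = self.minima[column], self.maxima[column]
        return (np.asarray(values, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


@dataclass
class ModelingDataset:
    """Complete-case daily modeling table plus its scaling parameters.

    ``records`` columns: date, the six covariates, mortality_rate, season.
    ``scaling`` covers the covariates and the response and is always fitted
    on the full (season-unfiltered) complete-case table so that Models I/II/III
    share one covariate scale.
    """

    records: pd.DataFrame
    scaling: MinMaxScaling
    season_filter: str = "all"
    covariate_names: tuple[str, ...] = tuple(COVARIATES)
    response_name: str = "mortality_rate"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def X(self) -> np.ndarray:
        return self.records[list(self.covariate_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.records[self.response_name].to_numpy(dtype=float)

    @property
    def X_scaled(self) -> np.ndarray:
        return np.column_stack(
            [self.scaling.scale_column(self.records[c].to_numpy(), c) for c in self.covariate_names]
        )

    @property
    def y_scaled(self) -> np.ndarray:
        return self.scaling.scale_column(self.y, self.response_name)

    def unscale_response(self, values: np.ndarray) -> np.ndarray:
        return self.scaling.unscale_column(values, self.response_name)

    def subset(self, indices: np.ndarray) -> "ModelingDataset":
        """Row subset sharing this dataset's scaling (used by the data splits)."""
        return ModelingDataset(
            records=self.records.iloc[indices].reset_index(drop=True),
            scaling=self.scaling,
            season_filter=self.season_filter,
            covariate_names=self.covariate_names,
            response_name=self.response_name,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.records.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        return path


def build_modeling_dataset(
    daily_covariates: pd.DataFrame,
    mortality: pd.DataFrame,
    season_filter: str = "all",
) -> ModelingDataset:
    """Merge covariates and mortality into the complete-case modeling table.

    ``daily_covariates``: date + the six covariate columns (NaN = missing).
    ``mortality``: date, deaths, elderly_population.
    Rows missing any covariate or the rate are dropped (listwise deletion);
    the season filter keeps 'all', 'rainy' or 'dry' rows.  Scaling
    parameters are fitted on the complete-case table *before* season
    filtering.
    """
    if season_filter not in ("all", "rainy", "dry"):
        raise ValueError(f"season_filter must be all/rainy/dry, got {season_filter!r}")
    cov = daily_covariates.copy()
    cov["date"] = pd.DatetimeIndex(cov["date"]).normalize()
    mort = mortality.copy()
    mort["date"] = pd.DatetimeIndex(mort["date"]).normalize()
    merged = cov.merge(mort, on="date", how="inner")
    merged["mortality_rate"] = [
        compute_mortality_rate(d, p) for d, p in zip(merged["deaths"], merged["elderly_population"])
    ]
    cols = ["date", *COVARIATES, "mortality_rate"]
    complete = merged[cols].dropna().reset_index(drop=True)
    if complete.empty:
        raise ValueError("no complete-case days survive filtering")
    complete["season"] = [assign_season(d) for d in complete["date"]]
    scaling = MinMaxScaling.fit(complete, [*COVARIATES, "mortality_rate"])
    if season_filter != "all":
        complete = complete[complete["season"] == season_filter].reset_index(drop=True)
        if complete.empty:
            raise ValueError(f"no days in season {season_filter!r}")
    return ModelingDataset(records=complete, scaling=scaling, season_filter=season_filter)


def load_hourly_csv(path: str | Path) -> list[HourlyStationSeries]:
    """Read the long-format hourly CSV (station_id,pollutant,timestamp,value)."""
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (station, pollutant), grp in frame.groupby(["station_id", "pollutant"], sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            HourlyStationSeries(
                station_id=str(station),
                pollutant=str(pollutant),
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return out


def load_meteorology_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, parse_dates=["date"])
    frame.columns = ["date", "temperature", "relative_humidity", "wind_speed"]
    return frame


def load_mortality_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def load_daily_table_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a pre-aggregated daily CSV (date + six covariates + deaths + population).

    Returns (daily_covariates, mortality) ready for
    :func:`build_modeling_dataset` — the adapter for user-supplied data in
    the cleaned-export shape.
    """
    frame = pd.read_csv(path, parse_dates=["date"])
    cov = frame[["date", *COVARIATES]]
    mort = frame[["date", "deaths", "elderly_population"]]
    return cov, mort
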