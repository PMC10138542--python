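import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from airmort import preprocess, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimulationConfig:
    """Two simulated years, two stations per pollutant."""
    return synthetic.SimulationConfig(
        start_date="2007-01-01",
        end_date="2008-12-31",
        n_stations_per_pollutant=2,
        seed=123,
    )


@pytest.fixture(scope="session")
def scenario(small_config) -> synthetic.SyntheticScenario:
    return synthetic.simulate_scenario(small_config)


@pytest.fixture(scope="session")
def daily_covariates(scenario) -> pd.DataFrame:
    pollutants = preprocess.pollutant_daily_table(scenario.hourly)
    return pollutants.merge(scenario.meteorology, on="date", how="inner")


@pytest.fixture(scope="session")
def dataset(daily_covariates, scenario) -> preprocess.ModelingDataset:
    return preprocess.build_modeling_dataset(daily_covariates, scenario.mortality)


@pytest.fixture(scope="session")
def affine_data():
    """Noiseless data exactly representable by a purelin-purelin network."""
    rng = np.random.default_rng(42)
    X = rng.uniform(-1.0, 1.0, size=(300, 4))
    beta = np.array([0.6, -0.4, 0.25, 0.1])
    y = X @ beta + 0.2
    return X[:200], y[:200], X[200:], y[200:]
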