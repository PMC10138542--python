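"""Verification studies: oracle-equivalence audits and recovery experiments.

These routines re-derive key behaviors of the package from scratch —
forward-pass agreement with a neuron-by-neuron scalar loop, t-statistics
against the first-principles formula, GLM coefficient recovery from data
simulated under the model, ground-truth importance ranking recovery, and
the benefit of season-stratified modelling — and return the measured
quantities.  They are what the acceptance checks and the reproduction
script execute.

Problem sizes are deliberately desk-scale (a few simulated years, reduced
architecture grids, tens of replicates): large enough for the effects to be
identifiable, small enough to re-run routinely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation, glm, importance, mlp, preprocess, search, synthetic
from .synthetic import COVARIATES


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# oracle equivalence


def scalar_loop_forward(params: mlp.MLPParameters, arch: mlp.MLPArchitecture, x: np.ndarray) -> float:
    """Neuron-by-neuron Python-loop network output; the forward-pass oracle."""
    a = [float(v) for v in x]
    for W, b, act in zip(params.weights, params.biases, arch.layer_activations):
        nxt = []
        for j in range(W.shape[1]):
            s = float(b[j])
            for i in range(W.shape[0]):
                s += float(W[i, j]) * a[i]
            nxt.append(float(mlp.activation(act, s)))
        a = nxt
    return a[0]


def forward_oracle_max_diff(n_networks: int = 100, seed: int = 0) -> float:
    """Max |vectorized − scalar-loop| output over random small networks (sizes ≤ 5)."""
    rng = np.random.default_rng(seed)
    acts = mlp.ACTIVATION_NAMES
    worst = 0.0
    for _ in range(n_networks):
        n_in = int(rng.integers(1, 6))
        hidden = tuple(int(rng.integers(1, 6)) for _ in range(int(rng.integers(1, 3))))
        arch = mlp.MLPArchitecture(
            n_in, hidden,
            hidden_activation=acts[rng.integers(3)],
            output_activation=acts[rng.integers(3)],
        )
        params = mlp.init_parameters(arch, rng)
        x = rng.normal(size=n_in)
        diff = abs(mlp.forward(params, arch, x[None, :])[0] - scalar_loop_forward(params, arch, x))
        worst = max(worst, diff)
    return worst


def ttest_formula_max_diff(n_pairs: int = 50, seed: int = 0) -> float:
    """Max |t − first-principles t| over random error-vector pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        na, nb = int(rng.integers(5, 200)), int(rng.integers(5, 200))
        a = rng.uniform(0.0, 50.0, na)
        b = rng.uniform(0.0, 50.0, nb)
        res = evaluation.compare_error_vectors(
            evaluation.ErrorVector("a", a), evaluation.ErrorVector("b", b)
        )
        df = na + nb - 2
        sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        worst = max(worst, abs(res.t_statistic - t_ref))
        assert res.degrees_of_freedom == df
    return worst


def toy_importance_percentages() -> tuple[float, float]:
    """Connection-weight percentages of the 2-input / 2-hidden reference network.

    Hand arithmetic: I = [[0.5, -1.0], [1.0, 0.0]], Imp = (-0.5, 1.0),
    percentages |−0.5|/1.5 and 1.0/1.5.
    """
    params = mlp.MLPParameters(
        [np.array([[1.0, -1.0], [2.0, 0.0]]), np.array([[0.5], [1.0]])],
        [np.zeros(2), np.zeros(1)],
    )
    res = importance.variable_importance(params)
    return float(res.importance_pct[0]), float(res.importance_pct[1])


# ---------------------------------------------------------------------------
# GLM parameter recovery


@dataclass
class GLMRecoveryResult:
    coverage_by_term: dict[str, float]   # fraction of replicates with |beta_hat-beta| < 3 SE
    min_coverage: float
    n_replicates: int
    n_obs: int


TRUE_GLM_BETA = {"intercept": 1.5, "pm10": 0.002, "no2": 0.001, "so2": -0.003}


def glm_recovery_study(n_replicates: int = 100, n_obs: int = 5000, seed: int = 0) -> GLMRecoveryResult:
    """Simulate rates from mu = exp(b0 + b·x) with gamma noise; refit; count 3-SE hits."""
    import pandas as pd

    hits = {t: 0 for t in ("pm10", "no2", "so2")}
    for rep in range(n_replicates):
        rng = np.random.default_rng(_subseed(seed, 10, rep))
        frame = {
            "date": pd.date_range("2007-01-01", periods=n_obs, freq="D"),
            "pm10": rng.uniform(15, 70, n_obs),
            "no2": rng.uniform(20, 80, n_obs),
            "so2": rng.uniform(1, 12, n_obs),
            "temperature": rng.uniform(10, 28, n_obs),
            "relative_humidity": rng.uniform(50, 95, n_obs),
            "wind_speed": rng.uniform(0.5, 5, n_obs),
        }
        frame = pd.DataFrame(frame)
        eta = TRUE_GLM_BETA["intercept"] + sum(
            TRUE_GLM_BETA[t] * frame[t].to_numpy() for t in ("pm10", "no2", "so2")
        )
        mu = np.exp(eta)
        shape = 20.0
        frame["mortality_rate"] = rng.gamma(shape=shape, scale=mu / shape)
        frame["season"] = "dry"
        scaling = preprocess.MinMaxScaling.fit(frame, [*COVARIATES, "mortality_rate"])
        ds = preprocess.ModelingDataset(records=frame, scaling=scaling)
        res = glm.fit_full_model(ds, glm.GLMSpec(basic_covariates=()), retained_basic_terms=())
        table = res.table.set_index("term")
        for t in hits:
            est = float(table.loc[t, "beta"])
            se = float(table.loc[t, "ci_high"] - table.loc[t, "ci_low"]) / (2 * 1.959963984540054)
            if abs(est - TRUE_GLM_BETA[t]) < 3 * se:
                hits[t] += 1
    coverage = {t: h / n_replicates for t, h in hits.items()}
    return GLMRecoveryResult(coverage, min(coverage.values()), n_replicates, n_obs)


# ---------------------------------------------------------------------------
# end-to-end scenario studies


def _reduced_grid(repeats: int = 10) -> search.SearchGrid:
    # the experimentation grid: the published best configuration's factors
    # (Levenberg-Marquardt, tansig/purelin) at two hidden sizes
    return search.SearchGrid(
        hidden_sizes=(5, 10),
        algorithms=("levenberg_marquardt",),
        activation_pairs=(("tansig", "purelin"),),
        repeats=repeats,
        max_epochs=150,
    )


def _dominant_weights(dominant: str = "pm10", weight: float = 0.7) -> dict[str, float]:
    rest = (1.0 - weight) / (len(COVARIATES) - 1)
    return {c: (weight if c == dominant else rest) for c in COVARIATES}


def _scenario_dataset(config: synthetic.SimulationConfig, season: str = "all") -> preprocess.ModelingDataset:
    sc = synthetic.simulate_scenario(config)
    pollutants = preprocess.pollutant_daily_table(sc.hourly)
    cov = pollutants.merge(sc.meteorology, on="date", how="inner")
    return preprocess.build_modeling_dataset(cov, sc.mortality, season_filter=season)


@dataclass
class ImportanceRecoveryResult:
    n_seeds: int
    top_rank_matches: int        # connection-weight top variable == ground truth
    oracle_agreements: int       # connection-weight top == permutation-oracle top
    pct_sum_max_error: float     # worst |sum(importance_pct) - 100|
    dominant: str


def importance_recovery_study(
    n_seeds: int = 10, seed: int = 0, dominant: str = "pm10", weight: float = 0.7,
    repeats: int = 10,
) -> ImportanceRecoveryResult:
    """End-to-end ranking recovery with one dominant ground-truth covariate.

    For each seed: simulate a scenario whose mortality loads ``weight`` on
    the dominant covariate, run the reduced grid search, and compare the
    best model's connection-weight top-ranked variable with the ground truth
    and with the permutation oracle.
    """
    matches = agreements = 0
    pct_err = 0.0
    for k in range(n_seeds):
        cfg = synthetic.SimulationConfig(
            start_date="2007-01-01",
            end_date="2009-12-31",
            n_stations_per_pollutant=2,
            effect_weights=_dominant_weights(dominant, weight),
            seed=_subseed(seed, 20, k),
        )
        ds = _scenario_dataset(cfg)
        result = search.run_search(ds, _reduced_grid(repeats), base_seed=_subseed(seed, 21, k))
        imp = importance.variable_importance(result.best_run.params, ds.covariate_names)
        pct_err = max(pct_err, abs(float(imp.importance_pct.sum()) - 100.0))
        cw_top = imp.variable_names[int(np.argmin(imp.ranks))]
        oracle = importance.permutation_importance_oracle(
            result.best_run.params,
            result.best_architecture,
            ds.X_scaled,
            ds.y_scaled,
            seed=_subseed(seed, 22, k),
            variable_names=ds.covariate_names,
        )
        oracle_top = oracle.variable_names[int(np.argmin(oracle.ranks))]
        matches += cw_top == dominant
        agreements += cw_top == oracle_top
    return ImportanceRecoveryResult(n_seeds, matches, agreements, pct_err, dominant)


@dataclass
class SeasonBenefitResult:
    n_seeds: int
    stratified_wins: int              # mean(MAPE_rainy, MAPE_dry) < MAPE_pooled
    mean_mape_pooled: float
    mean_mape_stratified: float
    df_checks_passed: int             # pooled-vs-season t-test df == n_a + n_b - 2


SEASONAL_WEIGHTS = {
    # the covariate-response relation flips between seasons: pollution-driven
    # mortality in the dry season, temperature-driven in the rainy season
    "dry": _dominant_weights("pm10", 0.7),
    "rainy": _dominant_weights("temperature", 0.7),
}


def season_benefit_study(n_seeds: int = 10, seed: int = 0, repeats: int = 10) -> SeasonBenefitResult:
    """Does season stratification beat the pooled model on season-dependent data?

    For each seed: simulate a scenario whose ground-truth effect weights
    differ by season, fit the pooled (all-data) model and the two
    season-stratified models with the same reduced grid, and compare the
    pooled MAPE with the mean of the two stratified MAPEs.  Also audits the
    pooled-vs-season t-test degree-of-freedom bookkeeping.
    """
    wins = df_ok = 0
    pooled_mapes, strat_mapes = [], []
    for k in range(n_seeds):
        cfg = synthetic.SimulationConfig(
            start_date="2007-01-01",
            end_date="2009-12-31",
            n_stations_per_pollutant=2,
            effect_weights_by_season=SEASONAL_WEIGHTS,
            seed=_subseed(seed, 30, k),
        )
        sc = synthetic.simulate_scenario(cfg)
        pollutants = preprocess.pollutant_daily_table(sc.hourly)
        cov = pollutants.merge(sc.meteorology, on="date", how="inner")
        ape = {}
        mape_by_season = {}
        for season in ("all", "rainy", "dry"):
            ds = preprocess.build_modeling_dataset(cov, sc.mortality, season_filter=season)
            res = search.run_search(ds, _reduced_grid(repeats), base_seed=_subseed(seed, 31, k))
            pred = mlp.predict_dataset(res.best_run.params, res.best_architecture, ds)
            ape[season] = evaluation.ape_vector(ds.y, pred, model_label=season)
            mape_by_season[season] = res.best_run.mape_all
        pooled = mape_by_season["all"]
        stratified = 0.5 * (mape_by_season["rainy"] + mape_by_season["dry"])
        pooled_mapes.append(pooled)
        strat_mapes.append(stratified)
        wins += stratified < pooled
        for season in ("rainy", "dry"):
            cmp_res = evaluation.compare_error_vectors(ape["all"], ape[season])
            df_ok += cmp_res.degrees_of_freedom == len(ape["all"]) + len(ape[season]) - 2
    return SeasonBenefitResult(
        n_seeds=n_seeds,
        stratified_wins=wins,
        mean_mape_pooled=float(np.mean(pooled_mapes)),
        mean_mape_stratified=float(np.mean(strat_mapes)),
        df_checks_passed=df_ok,
    )
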