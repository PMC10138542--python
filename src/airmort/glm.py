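"""Gamma / log-link GLM baseline with two-stage basic-model screening.

The classical comparator: the daily mortality rate (a strictly positive,
continuous response) is modelled as

    mu_i = exp(beta_0 + sum_k beta_k x_ik)

with a Gamma response distribution.  Following the epidemiological
convention, a *basic model* with the calendar and meteorology terms (month,
year, day of week, temperature, relative humidity, wind speed) is fitted
first; terms with p >= 0.05 are dropped, and the three pollutant
concentrations are then always added to the retained basic terms.

Fitting is delegated to statsmodels' IRLS (GLM with Gamma family and log
link); covariates enter on their natural scale so coefficients are per-unit
effects.  Month and day-of-week are categorical (11 and 6 dummies); year is
a numeric trend.  Dispersion is estimated by Pearson chi^2 / df and the
95% CIs are Wald intervals on the linear-predictor scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

BASIC_NUMERIC = ("year", "temperature", "relative_humidity", "wind_speed")
BASIC_CATEGORICAL = ("month", "day_of_week")
POLLUTANT_TERMS = ("pm10", "no2", "so2")


@dataclass
class GLMSpec:
    """Model specification: which terms enter, and the screening level."""

    basic_covariates: tuple[str, ...] = BASIC_CATEGORICAL + BASIC_NUMERIC
    pollutant_covariates: tuple[str, ...] = POLLUTANT_TERMS
    screening_alpha: float = 0.05
    family: str = "gamma"
    link: str = "log"

    def __post_init__(self) -> None:
        if not 0.0 < self.screening_alpha < 1.0:
            raise ValueError("screening_alpha must be in (0, 1)")
        if self.family != "gamma" or self.link != "log":
            raise ValueError("only the gamma family with log link is supported")


def _calendar_columns(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    dates = pd.DatetimeIndex(out["date"])
    out["month"] = dates.month
    out["year"] = dates.year
    out["day_of_week"] = dates.dayofweek
    return out


def build_design(records: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix with intercept; categorical terms expand to dummies.

    Dummy columns are named ``month[k]`` / ``day_of_week[k]`` with the first
    level as reference.
    """
    data = _calendar_columns(records)
    cols = {"Intercept": np.ones(len(data))}
    for term in terms:
        if term in BASIC_CATEGORICAL:
            levels = sorted(data[term].unique())
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (data[term] == level).astype(float)
        else:
            cols[term] = data[term].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def _term_of_column(column: str) -> str:
    return column.split("[", 1)[0]


@dataclass
class GLMResult:
    """Coefficient table, group screening p-values and fit diagnostics."""

    model_label: str
    terms: tuple[str, ...]
    table: pd.DataFrame            # term (column), beta, ci_low, ci_high, p_value
    term_pvalues: dict[str, float]  # per *term* (joint Wald for categorical groups)
    retained_terms: tuple[str, ...]
    deviance: float
    dispersion: float              # Pearson chi^2 / df_resid
    _design_columns: tuple[str, ...] = ()

    @property
    def coefficients(self) -> pd.Series:
        return self.table.set_index("term")["beta"]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.copy()
        out["model_label"] = self.model_label
        out.to_csv(path, index=False)
        return path


def _fit(design: pd.DataFrame, y: np.ndarray, model_label: str, spec: GLMSpec, terms: tuple[str, ...]) -> GLMResult:
    if (y <= 0).any():
        raise ValueError(
            "gamma GLM requires a strictly positive response; zero-death days are "
            "present — consider adding half the minimum positive rate as an offset"
        )
    # rank check with named columns for a useful error
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        _, R = np.linalg.qr(design.to_numpy())
        dependent = [design.columns[j] for j in range(design.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; offending columns: {dependent}")
    model = sm.GLM(y, design, family=sm.families.Gamma(link=sm.families.links.Log()))
    # start IRLS at the intercept-only solution; the default starting mu breaks
    # on degenerate (near-constant) responses
    start = np.zeros(design.shape[1])
    start[design.columns.get_loc("Intercept")] = np.log(float(np.mean(y)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(start_params=start)
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": design.columns,
            "beta": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    # per-term p-values: single Wald p for numeric terms, joint Wald for dummy groups
    term_pvalues: dict[str, float] = {}
    for term in terms:
        cols = [c for c in design.columns if _term_of_column(c) == term]
        if len(cols) == 1:
            term_pvalues[term] = float(fit.pvalues[cols[0]])
        else:
            R = np.zeros((len(cols), len(design.columns)))
            for r, c in enumerate(cols):
                R[r, design.columns.get_loc(c)] = 1.0
            term_pvalues[term] = float(np.squeeze(fit.wald_test(R, scalar=True).pvalue))
    retained = tuple(t for t in terms if term_pvalues[t] < spec.screening_alpha)
    return GLMResult(
        model_label=model_label,
        terms=terms,
        table=table,
        term_pvalues=term_pvalues,
        retained_terms=retained,
        deviance=float(fit.deviance),
        dispersion=float(fit.pearson_chi2 / fit.df_resid),
        _design_columns=tuple(design.columns),
    )


def fit_basic_model(dataset, spec: GLMSpec | None = None, model_label: str = "basic") -> GLMResult:
    """Stage 1: calendar + meteorology model; flags p >= alpha terms for exclusion."""
    spec = spec or GLMSpec()
    records = dataset.records
    design = build_design(records, spec.basic_covariates)
    return _fit(design, dataset.y, model_label, spec, spec.basic_covariates)


def fit_full_model(
    dataset,
    spec: GLMSpec | None = None,
    retained_basic_terms: tuple[str, ...] | None = None,
    model_label: str = "full",
) -> GLMResult:
    """Stage 2: retained basic terms + the three pollutants (always entered)."""
    spec = spec or GLMSpec()
    if retained_basic_terms is None:
        retained_basic_terms = fit_basic_model(dataset, spec).retained_terms
    terms = tuple(retained_basic_terms) + tuple(spec.pollutant_covariates)
    design = build_design(dataset.records, terms)
    return _fit(design, dataset.y, model_label, spec, terms)


def glm_predict(result: GLMResult, covariates: pd.DataFrame) -> np.ndarray:
    """Predicted rates mu = exp(linear predictor); strictly positive.

    ``covariates`` must carry a ``date`` column plus every retained numeric
    term; calendar terms are derived from the date.
    """
    design = build_design(covariates, result.terms)
    # align to the fitted design columns (unseen dummy levels get 0)
    aligned = pd.DataFrame(0.0, index=design.index, columns=list(result._design_columns))
    for c in design.columns:
        if c in aligned.columns:
            aligned[c] = design[c]
    beta = result.table.set_index("term")["beta"].reindex(result._design_columns).to_numpy()
    return np.exp(aligned.to_numpy() @ beta)


def glm_mape_errors(result: GLMResult, dataset) -> np.ndarray:
    """Per-observation absolute percentage errors of the GLM on a dataset."""
    mu = glm_predict(result, dataset.records)
    return 100.0 * np.abs(dataset.y - mu) / dataset.y
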