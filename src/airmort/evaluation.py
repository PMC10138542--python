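"""Error metrics and model-family comparisons.

MAPE (mean absolute percentage error) is the selection and comparison
metric; model families are compared by a pooled-variance two-sample t-test
on their per-observation absolute-percentage-error vectors, with
df = n_a + n_b - 2 (the pooled Student convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _validate(observed: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(f"length mismatch: {observed.shape} vs {predicted.shape}")
    if observed.size == 0:
        raise ValueError("empty input")
    if (observed <= 0).any():
        raise ValueError("observed values must be strictly positive for percentage errors")
    return observed, predicted


def mape(observed, predicted) -> float:
    """Mean of 100*|observed - predicted| / observed, in percent."""
    observed, predicted = _validate(observed, predicted)
    return float(np.mean(100.0 * np.abs(observed - predicted) / observed))


@dataclass
class ErrorVector:
    """Per-observation absolute percentage errors (%) for one model."""

    model_label: str
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        if (self.errors < 0).any() or not np.isfinite(self.errors).all():
            raise ValueError("APE entries must be finite and nonnegative")

    def __len__(self) -> int:
        return len(self.errors)

    @property
    def mean(self) -> float:
        return float(self.errors.mean())


def ape_vector(observed, predicted, model_label: str = "") -> ErrorVector:
    """Elementwise absolute percentage errors; mean equals :func:`mape`."""
    observed, predicted = _validate(observed, predicted)
    return ErrorVector(model_label, 100.0 * np.abs(observed - predicted) / observed)


@dataclass
class ComparisonResult:
    """Pooled two-sample t-test between two models' APE vectors."""

    model_a: str
    model_b: str
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_difference: float  # mean(a) - mean(b), percentage points


def compare_error_vectors(a: ErrorVector, b: ErrorVector) -> ComparisonResult:
    """Student (pooled-variance) two-sided t-test; df = n_a + n_b - 2."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both error vectors need at least 2 entries")
    na, nb = len(a), len(b)
    df = na + nb - 2
    var_a = float(a.errors.var(ddof=1))
    var_b = float(b.errors.var(ddof=1))
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = a.mean - b.mean
    t = diff / se if se > 0 else 0.0
    p = 1.0 if se == 0 and diff == 0 else 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(a.model_label, b.model_label, float(t), df, float(p), float(diff))


@dataclass
class DistributionSummary:
    """Five-number summary + mean + Tukey outliers (1.5*IQR fences)."""

    minimum: float
    q1: float
    median: float
    mean: float
    q3: float
    maximum: float
    outliers: np.ndarray

    def as_dict(self) -> dict:
        return {
            "min": self.minimum,
            "q1": self.q1,
            "median": self.median,
            "mean": self.mean,
            "q3": self.q3,
            "max": self.maximum,
            "n_outliers": len(self.outliers),
        }


def distribution_summary(values) -> DistributionSummary:
    """Boxplot-ready summary; quartiles use linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation default
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return DistributionSummary(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        mean=float(values.mean()),
        q3=float(q3),
        maximum=float(values.max()),
        outliers=outliers,
    )


def fraction_below(values, threshold: float) -> float:
    """Share of entries strictly below ``threshold`` (e.g. errors under 20%)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    return float((values < threshold).mean())


def comparison_report(pairs: list[tuple[ErrorVector, ErrorVector]]) -> pd.DataFrame:
    """Tabulate pairwise comparisons (model pair, t, df, p, mean MAPEs)."""
    rows = []
    for a, b in pairs:
        res = compare_error_vectors(a, b)
        rows.append(
            {
                "model_a": res.model_a,
                "model_b": res.model_b,
                "mape_a": a.mean,
                "mape_b": b.mean,
                "t_statistic": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p_value": res.p_value,
                "mean_difference": res.mean_difference,
            }
        )
    return pd.DataFrame(rows)


def boxplot_summary_frame(vectors: list[ErrorVector]) -> pd.DataFrame:
    """Distribution summaries of several models' errors, one row per model."""
    rows = []
    for v in vectors:
        d = distribution_summary(v.errors).as_dict()
        d["model"] = v.model_label
        rows.append(d)
    return pd.DataFrame(rows)[["model", "min", "q1", "median", "mean", "q3", "max", "n_outliers"]]
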