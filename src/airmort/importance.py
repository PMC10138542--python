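"""Connection-weight variable importance (Olden's method) for fitted MLPs.

For a single-hidden-layer network with one output, each input i's
contribution through hidden neuron j is the product of the input-to-hidden
weight and that neuron's hidden-to-output weight,

    I_ij = w_ij * w_j(out),

and the raw (signed) importance of input i is Imp_i = sum_j I_ij.  Reported
percentages normalize |Imp_i| to sum to 100; the signed values are kept
alongside because the sign carries the direction of association.

A permutation-importance oracle (mean MSE degradation when one input column
is shuffled) is provided as an independent ranking cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlp import MLPArchitecture, MLPParameters, forward


def connection_weights(params: MLPParameters) -> np.ndarray:
    """Contribution matrix I_ij (inputs × hidden neurons); biases excluded.

    Defined only for single-hidden-layer networks with one output.
    """
    if len(params.weights) != 2:
        raise ValueError("connection-weight importance requires exactly one hidden layer")
    w_hidden = params.hidden_weights            # (n_inputs, n_hidden)
    w_out = params.output_weights[:, 0]         # (n_hidden,)
    return w_hidden * w_out[None, :]


@dataclass
class ImportanceResult:
    """Connection-weight importances for one fitted network."""

    variable_names: tuple[str, ...]
    contribution_matrix: np.ndarray   # I_ij
    raw_importance: np.ndarray        # signed Imp_i
    importance_pct: np.ndarray        # |Imp_i| normalized to sum to 100
    ranks: np.ndarray                 # 1 = most important

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable_names,
                "importance_pct": self.importance_pct,
                "rank": self.ranks,
                "raw_importance": self.raw_importance,
            }
        )


def variable_importance(
    params: MLPParameters, variable_names: tuple[str, ...] | None = None
) -> ImportanceResult:
    """Signed importances, absolute-value percentages (sum 100), and ranks.

    Ties in percentage rank to the lower input index.  Raises on an all-zero
    importance vector (an untrained or degenerate network).
    """
    I = connection_weights(params)
    raw = I.sum(axis=1)
    total = np.abs(raw).sum()
    if total == 0:
        raise ValueError("all importances are exactly zero (untrained network?)")
    pct = np.abs(raw) / total * 100.0
    # stable argsort on descending pct -> ties go to the lower input index
    order = np.argsort(-pct, kind="stable")
    ranks = np.empty(len(pct), dtype=int)
    ranks[order] = np.arange(1, len(pct) + 1)
    names = variable_names or tuple(f"x{i + 1}" for i in range(len(raw)))
    if len(names) != len(raw):
        raise ValueError("variable_names length mismatch")
    return ImportanceResult(tuple(names), I, raw, pct, ranks)


@dataclass
class PermutationImportance:
    """Mean MSE degradation per shuffled input; the ranking oracle."""

    variable_names: tuple[str, ...]
    mse_increase: np.ndarray
    ranks: np.ndarray
    baseline_mse: float


def permutation_importance_oracle(
    params: MLPParameters,
    arch: MLPArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_permutations: int = 10,
    variable_names: tuple[str, ...] | None = None,
) -> PermutationImportance:
    """Average MSE increase over seeded shuffles of each input column."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    resid = forward(params, arch, X) - y
    baseline = float(resid @ resid / len(y))
    increases = np.zeros(X.shape[1])
    for i in range(X.shape[1]):
        acc = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, i] = Xp[rng.permutation(len(y)), i]
            r = forward(params, arch, Xp) - y
            acc += float(r @ r / len(y)) - baseline
        increases[i] = acc / n_permutations
    order = np.argsort(-increases, kind="stable")
    ranks = np.empty(len(increases), dtype=int)
    ranks[order] = np.arange(1, len(increases) + 1)
    names = variable_names or tuple(f"x{i + 1}" for i in range(X.shape[1]))
    return PermutationImportance(tuple(names), increases, ranks, baseline)
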