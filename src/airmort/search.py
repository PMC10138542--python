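"""Architecture grid search with the 70/15/15-split × repeated-training protocol.

Every architecture in the grid is trained ``repeats`` times, each repeat on
a fresh random 70/15/15 train/validation/test partition and a fresh seeded
weight initialization.  The winning run is the one with the lowest MAPE
computed over *all* observations of the dataset (the full real-vs-estimated
series), with ties broken by fewer hidden neurons, then lower test MSE,
then lower seed.  Searches are run separately for the pooled, rainy-season
and dry-season datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, mlp
from .preprocess import ModelingDataset

DEFAULT_ACTIVATION_PAIRS = tuple(itertools.product(mlp.ACTIVATION_NAMES, mlp.ACTIVATION_NAMES))


@dataclass(frozen=True)
class SearchGrid:
    """The architecture factors to cross.

    The default is the fully crossed single-hidden-layer grid: 7 sizes × 4
    algorithms × 9 activation pairs = 252 architectures; two-hidden-layer
    variants (equal sizes in both layers) can be enabled via
    ``layer_counts``.  Every factor is restrictable, and reduced grids are
    the norm for experimentation since the published best models all used
    Levenberg-Marquardt with tansig/purelin.
    """

    hidden_sizes: tuple[int, ...] = mlp.HIDDEN_SIZE_GRID
    layer_counts: tuple[int, ...] = (1,)
    algorithms: tuple[str, ...] = mlp.ALGORITHMS
    activation_pairs: tuple[tuple[str, str], ...] = DEFAULT_ACTIVATION_PAIRS
    repeats: int = 50
    max_epochs: int = 1000
    patience: int = 6

    def __post_init__(self) -> None:
        if not (self.hidden_sizes and self.layer_counts and self.algorithms and self.activation_pairs):
            raise ValueError("all grid factor sets must be nonempty")
        bad = set(self.hidden_sizes) - set(mlp.HIDDEN_SIZE_GRID)
        if bad:
            raise ValueError(f"hidden sizes outside the {mlp.HIDDEN_SIZE_GRID} grid: {sorted(bad)}")
        if set(self.layer_counts) - {1, 2}:
            raise ValueError("layer_counts must be a subset of {1, 2}")
        if set(self.algorithms) - set(mlp.ALGORITHMS):
            raise ValueError("unknown algorithm in grid")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def enumerate_grid(grid: SearchGrid, n_inputs: int = 6) -> list[mlp.MLPArchitecture]:
    """Cartesian product of the grid factors in a stable, documented order.

    Order: layer count, then hidden size, then algorithm, then activation
    pair — each in the order given by the grid fields.
    """
    archs = []
    for layers in grid.layer_counts:
        for size in grid.hidden_sizes:
            for algorithm in grid.algorithms:
                for hidden_act, output_act in grid.activation_pairs:
                    archs.append(
                        mlp.MLPArchitecture(
                            n_inputs=n_inputs,
                            hidden_sizes=(size,) * layers,
                            hidden_activation=hidden_act,
                            output_activation=output_act,
                            algorithm=algorithm,
                        )
                    )
    return archs


def split_data(
    dataset: ModelingDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[ModelingDataset, ModelingDataset, ModelingDataset]:
    """Random disjoint train/validation/test partition.

    Sizes are floor(f_train*n), floor(f_val*n) and the remainder; all three
    subsets share the parent dataset's scaling parameters.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(dataset)
    if n < 10:
        raise ValueError(f"dataset too small to split ({n} rows)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return (
        dataset.subset(perm[:n_train]),
        dataset.subset(perm[n_train : n_train + n_val]),
        dataset.subset(perm[n_train + n_val :]),
    )


def _derive_seeds(base_seed: int, config_index: int, repeat: int) -> tuple[int, int]:
    """Deterministic (split_seed, init_seed) pair below 2^31 per run."""
    ss = np.random.SeedSequence([int(base_seed), int(config_index), int(repeat)])
    split_seed, init_seed = ss.generate_state(2) % (2**31)
    return int(split_seed), int(init_seed)


def _run_one(
    arch: mlp.MLPArchitecture,
    dataset: ModelingDataset,
    split_seed: int,
    init_seed: int,
    max_epochs: int,
    patience: int,
) -> mlp.TrainingResult:
    train_set, val_set, test_set = split_data(dataset, seed=split_seed)
    result = mlp.train(
        arch,
        train_set.X_scaled,
        train_set.y_scaled,
        val_set.X_scaled,
        val_set.y_scaled,
        seed=init_seed,
        max_epochs=max_epochs,
        patience=patience,
    )
    if not result.failed:
        result.mse_test = mlp._mse(result.params, arch, test_set.X_scaled, test_set.y_scaled)
        pred_all = mlp.predict_dataset(result.params, arch, dataset)
        if np.isfinite(pred_all).all():
            result.mape_all = evaluation.mape(dataset.y, pred_all)
            pred_test = mlp.predict_dataset(result.params, arch, test_set)
            result.mape_test = evaluation.mape(test_set.y, pred_test)
        else:
            result.failed = True
    return result


@dataclass
class SearchResult:
    """All runs of a grid search plus the selected best run."""

    runs: list[tuple[mlp.MLPArchitecture, mlp.TrainingResult]]
    best_architecture: mlp.MLPArchitecture
    best_run: mlp.TrainingResult
    mape_range: tuple[float, float]
    n_failed: int
    season: str = "all"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arch, res in self.runs:
            rows.append(
                {
                    "hidden_sizes": "x".join(map(str, arch.hidden_sizes)),
                    "hidden_activation": arch.hidden_activation,
                    "output_activation": arch.output_activation,
                    "algorithm": arch.algorithm,
                    "seed": res.seed,
                    "epochs_run": res.epochs_run,
                    "mse_train": res.mse_train,
                    "mse_val": res.mse_val,
                    "mse_test": res.mse_test,
                    "mape_all": res.mape_all,
                    "mape_test": res.mape_test,
                    "failed": res.failed,
                }
            )
        return pd.DataFrame(rows)


def _selection_key(arch: mlp.MLPArchitecture, res: mlp.TrainingResult):
    return (res.mape_all, sum(arch.hidden_sizes), res.mse_test, res.seed)


def run_search(dataset: ModelingDataset, grid: SearchGrid, base_seed: int = 0, season: str | None = None) -> SearchResult:
    """Train every architecture ``grid.repeats`` times and select by MAPE."""
    archs = enumerate_grid(grid, n_inputs=len(dataset.covariate_names))
    runs: list[tuple[mlp.MLPArchitecture, mlp.TrainingResult]] = []
    n_failed = 0
    for ci, arch in enumerate(archs):
        for rep in range(grid.repeats):
            split_seed, init_seed = _derive_seeds(base_seed, ci, rep)
            res = _run_one(arch, dataset, split_seed, init_seed, grid.max_epochs, grid.patience)
            if res.failed:
                n_failed += 1
            runs.append((arch, res))
    ok = [(a, r) for a, r in runs if not r.failed]
    if not ok:
        raise RuntimeError("every training run of every configuration failed")
    best_arch, best_run = min(ok, key=lambda ar: _selection_key(*ar))
    mapes = [r.mape_all for _, r in ok]
    return SearchResult(
        runs=runs,
        best_architecture=best_arch,
        best_run=best_run,
        mape_range=(float(min(mapes)), float(max(mapes))),
        n_failed=n_failed,
        season=season or dataset.season_filter,
    )


def mse_distribution(
    best_architecture: mlp.MLPArchitecture,
    dataset: ModelingDataset,
    repeats: int = 50,
    base_seed: int = 0,
    max_epochs: int = 1000,
    patience: int = 6,
) -> evaluation.DistributionSummary:
    """Training-MSE distribution of one architecture over repeated seeded runs."""
    mses = []
    for rep in range(repeats):
        split_seed, init_seed = _derive_seeds(base_seed, 0, rep)
        res = _run_one(best_architecture, dataset, split_seed, init_seed, max_epochs, patience)
        if not res.failed:
            mses.append(res.mse_train)
    if not mses:
        raise RuntimeError("all repeated trainings failed")
    return evaluation.distribution_summary(np.array(mses))


def save_search(result: SearchResult, out_dir: str | Path) -> dict[str, Path]:
    """Persist the run table (CSV) and the best model's weights (text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "runs": out / f"search_runs_{result.season}.csv",
        "weights": out / f"best_weights_{result.season}.txt",
    }
    result.to_frame().to_csv(paths["runs"], index=False)
    paths["weights"].write_text(mlp.params_to_text(result.best_run.params, result.best_architecture))
    return paths
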