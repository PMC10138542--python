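"""End-to-end orchestration: simulate → preprocess → train → importance → GLM → evaluate.

One master seed fans out deterministically to every stage through
``numpy.random.SeedSequence([master_seed, stage_index])``; no stage touches
global random state, so a rerun with the same config reproduces every
artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, glm, importance, mlp, preprocess, search, synthetic

_STAGE = {"simulate": 0, "split": 1, "train": 2, "importance": 3, "glm": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master_seed), _STAGE[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``scenario`` (synthetic mode) or ``input_paths`` (real-data mode:
    hourly/meteorology/mortality CSVs, or a single pre-aggregated daily CSV
    under the key 'daily') must be provided.
    """

    output_dir: str = "airmort_run"
    scenario: synthetic.SimulationConfig | None = None
    input_paths: dict[str, str] | None = None
    grid: search.SearchGrid = field(default_factory=search.SearchGrid)
    glm_spec: glm.GLMSpec = field(default_factory=glm.GLMSpec)
    seasons_to_run: tuple[str, ...] = ("all", "rainy", "dry")
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.seasons_to_run:
            raise ValueError("seasons_to_run must be nonempty")
        if set(self.seasons_to_run) - {"all", "rainy", "dry"}:
            raise ValueError("seasons_to_run entries must be all/rainy/dry")
        if self.scenario is None and self.input_paths is None:
            raise ValueError("either a synthetic scenario or input paths must be given")
        if self.input_paths is not None:
            missing = [p for p in self.input_paths.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input paths do not exist: {missing}")

    def config_hash(self) -> str:
        payload = json.dumps(_serialize(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialize(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    return obj


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (daily_covariates, mortality)."""
    if config.scenario is not None:
        scenario = synthetic.simulate_scenario(
            dataclasses.replace(config.scenario, seed=stage_seed(config.master_seed, "simulate"))
        )
        pollutants = preprocess.pollutant_daily_table(scenario.hourly)
        met = scenario.meteorology
        cov = pollutants.merge(met, on="date", how="inner")
        return cov, scenario.mortality
    paths = config.input_paths
    if "daily" in paths:
        return preprocess.load_daily_table_csv(paths["daily"])
    hourly = preprocess.load_hourly_csv(paths["hourly"])
    pollutants = preprocess.pollutant_daily_table(hourly)
    met = preprocess.load_meteorology_csv(paths["meteorology"])
    cov = pollutants.merge(met, on="date", how="inner")
    return cov, preprocess.load_mortality_csv(paths["mortality"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for each requested season; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "artifacts": {},
        "metrics": {},
    }

    cov, mort = _load_inputs(config)
    ape_by_season: dict[str, evaluation.ErrorVector] = {}
    glm_ape_by_season: dict[str, evaluation.ErrorVector] = {}

    for season in config.seasons_to_run:
        dataset = preprocess.build_modeling_dataset(cov, mort, season_filter=season)
        dataset.to_csv(out / f"modeling_table_{season}.csv")

        result = search.run_search(dataset, config.grid, base_seed=stage_seed(config.master_seed, "train"), season=season)
        paths = search.save_search(result, out)
        manifest["artifacts"][f"search_{season}"] = str(paths["runs"])
        manifest["artifacts"][f"weights_{season}"] = str(paths["weights"])
        manifest["metrics"][f"ann_mape_{season}"] = result.best_run.mape_all
        manifest["metrics"][f"ann_best_hidden_{season}"] = list(result.best_architecture.hidden_sizes)
        manifest["metrics"][f"ann_failed_runs_{season}"] = result.n_failed

        pred = mlp.predict_dataset(result.best_run.params, result.best_architecture, dataset)
        ape_by_season[season] = evaluation.ape_vector(dataset.y, pred, model_label=f"ANN_{season}")

        if len(result.best_architecture.hidden_sizes) == 1:
            imp = importance.variable_importance(
                result.best_run.params, variable_names=dataset.covariate_names
            )
            imp_path = out / f"importance_{season}.csv"
            imp.to_frame().to_csv(imp_path, index=False)
            manifest["artifacts"][f"importance_{season}"] = str(imp_path)
            manifest["metrics"][f"top_variable_{season}"] = imp.variable_names[int(np.argmin(imp.ranks))]

        basic = glm.fit_basic_model(dataset, config.glm_spec, model_label=f"basic_{season}")
        full = glm.fit_full_model(
            dataset, config.glm_spec, retained_basic_terms=basic.retained_terms, model_label=f"GLM_{season}"
        )
        glm_path = out / f"glm_table_{season}.csv"
        full.to_csv(glm_path)
        manifest["artifacts"][f"glm_{season}"] = str(glm_path)
        glm_errors = glm.glm_mape_errors(full, dataset)
        glm_ape_by_season[season] = evaluation.ErrorVector(f"GLM_{season}", glm_errors)
        manifest["metrics"][f"glm_mape_{season}"] = float(glm_errors.mean())
        manifest["metrics"][f"glm_excluded_terms_{season}"] = [
            t for t in config.glm_spec.basic_covariates if t not in basic.retained_terms
        ]

    pairs = []
    if "all" in ape_by_season:
        for season in ("rainy", "dry"):
            if season in ape_by_season:
                pairs.append((ape_by_season["all"], ape_by_season[season]))
    for season, ann_vec in ape_by_season.items():
        if season in glm_ape_by_season:
            pairs.append((ann_vec, glm_ape_by_season[season]))
    if pairs:
        report = evaluation.comparison_report(pairs)
        report_path = out / "comparison_report.csv"
        report.to_csv(report_path, index=False)
        manifest["artifacts"]["comparisons"] = str(report_path)
    box = evaluation.boxplot_summary_frame(list(ape_by_season.values()) + list(glm_ape_by_season.values()))
    box_path = out / "error_distributions.csv"
    box.to_csv(box_path, index=False)
    manifest["artifacts"]["error_distributions"] = str(box_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
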