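"""Experiment orchestration: configuration, seeding, artifacts.

One ``ExperimentConfig`` (YAML-serialisable) drives the whole chain
simulate -> filter -> preprocess -> featurize -> LOOCV -> importance,
writing every intermediate artifact to disk.  A single master seed
derives all random streams, so re-running a config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .api import OveruseInjuryModel
from .cohort import CohortConfig, CohortError, generate_cohort, write_cohort
from .features import BankConfig, build_feature_table
from .filtering import apply_inclusion_criteria
from .importance import feature_budget, feature_occurrence, group_exclusion_analysis
from .model import ModelConfig
from .preprocessing import preprocess_cohort, write_signal_cache

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """User-facing configuration problem (CLI exit code 1)."""


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bank: BankConfig = field(default_factory=BankConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_bins: int = 256
    pool_feet: bool = True
    importance_budget: int | None = None  # None -> 10% rule
    occurrence_threshold: float = 0.10
    run_importance: bool = True
    out_dir: str = "plantarpress_run"
    seed: int = 0

    def __post_init__(self) -> None:
        # the master seed overrides the cohort seed so one integer
        # controls the whole experiment
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["k_grid"] = list(d["model"]["k_grid"])
        for key in ("stance_duration_run", "stance_duration_walk"):
            d["cohort"][key] = list(d["cohort"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        try:
            cohort = d.pop("cohort", {})
            for key in ("stance_duration_run", "stance_duration_walk"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            model = d.pop("model", {})
            if "k_grid" in model:
                model["k_grid"] = tuple(model["k_grid"])
            return cls(cohort=CohortConfig(**cohort),
                       bank=BankConfig(**d.pop("bank", {})),
                       model=ModelConfig(**model), **d)
        except TypeError as exc:
            raise ConfigError(f"invalid experiment config: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2))


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline and write all artifacts under
    ``config.out_dir``.  Returns the metrics dictionary."""
    t0 = time.perf_counter()
    try:
        config.cohort.validate()
    except CohortError as exc:
        raise ConfigError(str(exc)) from exc
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(msg: str) -> None:
        logger.info("[%7.2fs] %s", time.perf_counter() - t0, msg)

    stage("simulating cohort")
    store, profiles, roster = generate_cohort(config.cohort)
    write_cohort(out, store, profiles, roster, config.cohort)

    stage("applying inclusion criteria")
    inclusion = apply_inclusion_criteria(roster)
    _write_json(out / "inclusion_counts.json",
                {"n_included": inclusion.n_included,
                 "class_counts": inclusion.class_counts})

    stage("aligning and normalising trials")
    signal_sets, align_info = preprocess_cohort(
        store, subject_ids=inclusion.included_ids,
        n_bins=config.n_bins, pool_feet=config.pool_feet)
    write_signal_cache(out, signal_sets, align_info)

    stage("extracting features")
    included = set(inclusion.included_ids)
    table = build_feature_table(signal_sets,
                                [p for p in profiles if p.subject_id in included],
                                config.bank)
    table.to_csv(out / "features.csv")
    _write_json(out / "features_schema.json", {
        "n_subjects": int(table.shape[0]),
        "n_features": int(table.shape[1] - 1),
        "column_grammar": "zone|measurement|footwear|feature_id",
        "bank": dataclasses.asdict(config.bank),
    })

    stage("leave-one-out cross-validation")
    model = OveruseInjuryModel(table, config.model)
    results = model.fit()
    results.predictions.to_csv(out / "predictions.csv", index=False)
    results.fold_summary.to_csv(out / "folds.csv", index=False)

    y = results.loocv.labels
    metrics = {
        "auc": results.auc,
        "brier": results.brier,
        "n_subjects": results.nobs,
        "n_healthy": int((y == 0).sum()),
        "n_injured": int((y == 1).sum()),
        "mean_k_best": results.loocv.mean_k_best,
        "mean_nonzero_weights": results.loocv.mean_nonzero,
    }
    _write_json(out / "metrics.json", metrics)

    occurrence = feature_occurrence(results.loocv, config.occurrence_threshold)
    occurrence.to_csv(out / "feature_occurrence.csv", index=False)

    if config.run_importance:
        stage("group-exclusion importance analysis")
        budget = config.importance_budget or feature_budget(results.nobs)
        impact, _ = group_exclusion_analysis(table, config.model, budget=budget)
        impact.to_csv(out / "group_impact.csv", index=False)

    _write_json(out / "manifest.json", {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "config": config.to_dict(),
    })
    config.to_yaml(out / "config.yaml")
    stage("done")
    return metrics


def run_synthetic_experiment(
    n_subjects: int,
    effect_size: float,
    seed: int,
    model_config: ModelConfig | None = None,
    run_importance: bool = False,
    injured_fraction: float = 35 / 155,
) -> dict:
    """In-memory end-to-end run on a synthetic cohort; returns the pooled
    metrics plus (optionally) the group-impact table.  Shared by the
    acceptance checks and the worked examples."""
    cfg = CohortConfig(n_subjects=n_subjects, effect_size=effect_size,
                       injured_fraction=injured_fraction, seed=seed)
    model = OveruseInjuryModel.from_cohort(cfg, config=model_config)
    results = model.fit()
    outcome = {
        "auc": results.auc,
        "brier": results.brier,
        "n_subjects": results.nobs,
        "results": results,
    }
    if run_importance:
        outcome["group_impact"] = results.group_importance()
    return outcome
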