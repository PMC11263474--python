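"""End-to-end pipeline: simulate -> impute -> filter -> metrics -> features
-> train/compare -> explain, with a manifest for reproducibility.

Every stage writes plain delimited text or JSON into the run
directory, so any stage can be inspected or replaced.  A master seed
deterministically derives one sub-seed per stage (recorded in the
manifest) so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cgm as cgm_mod
from . import impute as impute_mod
from .attribution import feature_correlations, rank_features, shap_values
from .cohort import CohortConfig, simulate_cohort
from .features import FEATURE_NAMES, build_feature_table
from .meals import apply_filters, load_meals, save_meals
from .metrics import build_response_table
from .model import FitResult, run_comparison, split_meals

STAGE_NAMES = ("simulate", "impute", "filter", "metrics", "features", "train", "explain")


@dataclass
class PipelineConfig:
    """All options of a pipeline run, validated up front."""

    out_dir: str = "run"
    seed: int = 0
    n_patients: int = 13
    days_per_patient: int = 14
    missing_fraction: float = 0.10
    gain_epochs: int = 150
    baseline_window: str = "pre"
    clip_negative: bool = False
    adjacent_policy: str = "both"
    trend_sign: str = "rising"
    n_trials: int = 25
    grouped_split: bool = False
    top_k: int = 20

    def validate(self) -> None:
        if self.baseline_window not in ("pre", "post"):
            raise ValueError(f"invalid baseline_window {self.baseline_window!r}")
        if self.adjacent_policy not in ("both", "later"):
            raise ValueError(f"invalid adjacent_policy {self.adjacent_policy!r}")
        if self.trend_sign not in ("rising", "literal"):
            raise ValueError(f"invalid trend_sign {self.trend_sign!r}")
        if not 0 <= self.missing_fraction <= 0.5:
            raise ValueError("missing_fraction must lie in [0, 0.5]")
        if self.n_trials < 1 or self.gain_epochs < 1:
            raise ValueError("n_trials and gain_epochs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one recorded sub-seed per stage from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGE_NAMES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "stage_seeds": seeds, "stages": {}}

    # --- simulate
    cohort = simulate_cohort(
        CohortConfig(
            n_patients=config.n_patients,
            days_per_patient=config.days_per_patient,
            seed=seeds["simulate"],
            missing_fraction=config.missing_fraction,
        )
    )
    cohort.profiles.to_csv(out / "profiles.csv", index=False)
    save_meals(cohort.meals, out / "meals_recorded.csv")
    cgm_mod.save_cgm(cohort.cgm.values(), out / "cgm.csv")
    manifest["stages"]["simulate"] = {
        "n_patients": len(cohort.profiles),
        "meals_recorded": len(cohort.meals),
    }

    # --- impute
    observed_masks = {
        pid: ~np.isnan(s.values) for pid, s in cohort.cgm.items()
    }
    imputed = impute_mod.impute_series(
        cohort.cgm, method="gain", gain_epochs=config.gain_epochs, seed=seeds["impute"]
    )
    cgm_mod.save_cgm(imputed.values(), out / "cgm_imputed.csv")
    manifest["stages"]["impute"] = {
        "method": "gain",
        "epochs": config.gain_epochs,
        "missing_fraction": float(
            np.mean([np.isnan(s.values).mean() for s in cohort.cgm.values()])
        ),
    }

    # --- filter
    kept, verdicts, summary = apply_filters(
        cohort.meals, adjacent_policy=config.adjacent_policy
    )
    save_meals(kept, out / "meals_kept.csv")
    verdicts.to_csv(out / "filter_verdicts.csv", index=False)
    manifest["stages"]["filter"] = summary.to_dict()

    # --- metrics
    responses, rejected = build_response_table(
        kept,
        imputed,
        observed_masks,
        baseline_window=config.baseline_window,
        clip_negative=config.clip_negative,
    )
    responses.to_csv(out / "responses.csv", index=False)
    rejected.to_csv(out / "responses_rejected.csv", index=False)
    manifest["stages"]["metrics"] = {
        "responses": len(responses),
        "rejected": len(rejected),
    }

    # --- features
    table, feat_rejected = build_feature_table(
        kept, cohort.profiles, imputed, responses, trend_sign=config.trend_sign
    )
    table.to_csv(out / "features.csv", index=False)
    manifest["stages"]["features"] = {
        "meals": len(table),
        "rejected": len(feat_rejected),
        "n_features": len(FEATURE_NAMES),
    }

    # --- train/compare
    results = run_comparison(
        table,
        seed=seeds["train"],
        n_trials=config.n_trials,
        grouped=config.grouped_split,
    )
    comparison = {
        f"{target}/{variant}": res.summary()
        for (target, variant), res in results.items()
    }
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
    manifest["stages"]["train"] = {
        k: {"pearson_r": v["pearson_r"], "explained_variance": v["explained_variance"]}
        for k, v in comparison.items()
    }

    # --- explain (full PPGR model, validation split)
    _, val = split_meals(table, seed=seeds["train"], grouped=config.grouped_split)
    full_model = results[("ppgr", "full")].model
    attr = shap_values(full_model, val[FEATURE_NAMES])
    attr.shap_values.to_csv(out / "shap_values.csv", index=False)
    ranking = rank_features(attr, k=config.top_k)
    ranking.to_csv(out / "ranking.csv", index=False)
    corr = feature_correlations(table[FEATURE_NAMES], table["ppgr"].rename("ppgr"))
    corr.to_csv(out / "correlations.csv")
    manifest["stages"]["explain"] = {
        "top_features": ranking["feature"].head(5).tolist(),
        "max_additivity_residual": float(
            np.abs(
                attr.base_values + attr.shap_values.sum(axis=1).to_numpy()
                - attr.predictions
            ).max()
        ),
    }

    manifest["counts_reconcile"] = {
        "meals_recorded": len(cohort.meals),
        "meals_kept": len(kept),
        "rejected_by_filter": len(cohort.meals) - len(kept),
        "rejected_by_metrics": len(rejected),
        "modelled": len(table),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
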