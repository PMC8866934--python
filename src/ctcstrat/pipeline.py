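"""End-to-end orchestration: aggregate -> rank -> {single variable, screen}
-> survival / contingency, with a reproducible run manifest.

A single configuration object (optionally loaded from YAML) is the sole
source of parameters.  Outputs are plain text (CSV/TSV/JSON) and contain
no timestamps, so re-running an archived configuration reproduces every
artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .aggregate import CohortMatrix, build_matrix
from .cohort import Cohort, read_cohort
from .errors import ConfigError
from .featselect import rank_features
from .screening import ModelResult, screen
from .singlevar import contingency_metrics, loo_single_variable
from .survival import km_estimate, logrank

log = logging.getLogger("ctcstrat")


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run."""

    cells_path: str = "cells.csv"
    clinical_path: str = "clinical.csv"
    out_dir: Optional[str] = None
    target: str = "OS"                  # OS | BM
    cell_class: str = "eCTC"            # eCTC | CD45pos | both
    os_threshold_months: float = 30.0
    k_bins: int = 4
    alpha: float = 1.0
    top_k: int = 10
    families: tuple[str, ...] = ("naive_bayes", "logistic_regression",
                                 "decision_tree", "random_forest")
    discretize_scope: str = "fold"      # fold | cohort
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.os_threshold_months <= 0:
            raise ConfigError("os_threshold_months must be positive")
        if not (1 <= self.top_k <= 20):
            raise ConfigError("top_k must lie in [1, 20]")
        if self.target not in ("OS", "BM"):
            raise ConfigError("target must be OS or BM")
        if self.discretize_scope not in ("fold", "cohort"):
            raise ConfigError("discretize_scope must be fold or cohort")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig,
                 cohort: Optional[Cohort] = None) -> dict:
    """Execute the full analysis; optionally write a report bundle.

    Returns a dict with the cohort matrix, feature ranking, single-variable
    result, screening leaderboard and best model, the survival or
    contingency summary, and the run manifest.
    """
    config.validate()
    if cohort is None:
        directory = Path(config.cells_path).parent
        log.info("reading cohort from %s", directory)
        cohort = read_cohort(directory, os_threshold=config.os_threshold_months)
    log.info("cohort: %d cells, %d patients", len(cohort.cells), len(cohort.clinical))

    matrix = build_matrix(cohort, cls=config.cell_class, target=config.target,
                          os_threshold=config.os_threshold_months)
    log.info("matrix: %d patients x %d features (target %s, class %s)",
             len(matrix.X), len(matrix.feature_names), config.target, config.cell_class)

    ranking = rank_features(matrix, k_bins=config.k_bins, top=config.top_k)
    top = ranking.top(config.top_k)
    log.info("top feature: %s (IG %.3f bits)", *ranking.ranking[0])

    sv = loo_single_variable(matrix, top[0])
    log.info("single-variable LOO accuracy: %.3f", sv.metrics.accuracy)

    best, leaderboard = screen(
        matrix, top, families=config.families, k_bins=config.k_bins,
        alpha=config.alpha, seed=config.seed,
        discretize_scope=config.discretize_scope,
        hyperparameters=config.hyperparameters,
    )
    log.info("best model: %s on %d features, LOO accuracy %.3f",
             best.spec.family, best.n_features, best.loo_accuracy)

    bundle: dict = {
        "matrix": matrix,
        "ranking": ranking,
        "single_variable": sv,
        "leaderboard": leaderboard,
        "best_model": best,
        "best_metrics": contingency_metrics(best.loo_predictions, matrix.y),
    }
    if config.target == "OS":
        bundle["survival"] = _survival_summary(matrix, best)
    bundle["manifest"] = _manifest(config, cohort, matrix, best)

    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _survival_summary(matrix: CohortMatrix, best: ModelResult) -> dict:
    """KM curves and log-rank on the LOO-predicted strata."""
    groups = best.loo_predictions
    curves = {
        "predicted_long": km_estimate(matrix.os_months[groups],
                                      matrix.os_event[groups], "predicted_long"),
        "predicted_short": km_estimate(matrix.os_months[~groups],
                                       matrix.os_event[~groups], "predicted_short"),
    }
    lr = logrank(matrix.os_months, matrix.os_event, groups)
    return {"curves": curves, "logrank": lr,
            "medians": {k: c.median for k, c in curves.items()}}


def _manifest(config: PipelineConfig, cohort: Cohort, matrix: CohortMatrix,
              best: ModelResult) -> dict:
    return {
        "ctcstrat_version": __version__,
        "config": {**asdict(config), "families": list(config.families)},
        "n_cells": len(cohort.cells),
        "n_patients": len(cohort.clinical),
        "n_patients_analyzed": len(matrix.X),
        "best_family": best.spec.family,
        "best_subset": list(best.feature_subset),
        "best_loo_accuracy": best.loo_accuracy,
    }


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["matrix"].to_csv(out / "matrix.csv")
    with open(out / "ranking.tsv", "w") as fh:
        fh.write("feature\tinformation_gain_bits\trank\n")
        for i, (name, gain) in enumerate(bundle["ranking"].ranking, 1):
            fh.write(f"{name}\t{gain:.6f}\t{i}\n")
    bundle["leaderboard"].to_csv(out / "leaderboard.csv", index=False)
    sv = bundle["single_variable"]
    with open(out / "singlevar.json", "w") as fh:
        json.dump(
            {
                "feature": sv.feature,
                "predictions": [bool(p) for p in sv.predictions],
                "cutoffs": [
                    {"cutoff": c.cutoff, "orientation": c.orientation,
                     "youden_J": c.youden_j}
                    for c in sv.cutoffs
                ],
                "metrics": sv.metrics.as_dict(),
            },
            fh, indent=1,
        )
    best = bundle["best_model"]
    with open(out / "best_model.json", "w") as fh:
        json.dump(
            {
                "family": best.spec.family,
                "features": list(best.feature_subset),
                "loo_accuracy": best.loo_accuracy,
                "predictions": [bool(p) for p in best.loo_predictions],
                "contingency": bundle["best_metrics"].as_dict(),
            },
            fh, indent=1,
        )
    if "survival" in bundle:
        import pandas as pd

        tables = []
        for name, curve in bundle["survival"]["curves"].items():
            t = curve.as_table()
            t.insert(0, "group", name)
            tables.append(t)
        pd.concat(tables).to_csv(out / "km.tsv", sep="\t", index=False)
        lr = bundle["survival"]["logrank"]
        with open(out / "logrank.json", "w") as fh:
            json.dump(
                {
                    "statistic": lr.statistic,
                    "p_value": lr.p_value,
                    "observed": lr.observed.tolist(),
                    "expected": lr.expected.tolist(),
                    "medians": bundle["survival"]["medians"],
                },
                fh, indent=1,
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1, sort_keys=True)
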