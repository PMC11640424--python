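"""End-to-end orchestration: split → prepare → select pairs → fit → evaluate.

Two presets mirror the two diagnostic questions the pipeline serves:

* ``itlb1`` — non-mucinous vs mucinous: train on the samples with a
  confirmed diagnosis, apply the fitted scorer to the high-probability rest
  as a validation set;
* ``itlb2`` — benign vs malignant mucinous: train on every labeled sample
  (cohorts this small leave nothing to hold out), no validation split.

:func:`run_train` returns the fitted model plus training confusion metrics,
ROC/AUC and a validation score table, and can persist model JSON, score CSV,
metrics JSON and a run log stamped with the config hash and package version.
All randomness (CV folds, bootstrap) flows from the seeds in the config, so
a rerun with identical config and cohort reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, TlbError
from .evaluate import ConfusionSummary, ROCResult, confusion_metrics, make_score_table, roc_auc, wilcoxon_rank_sum
from .io import Cohort
from .model import FittedModel, fit, grid_hash, score_features, train_validate_split
from .preprocess import DEFAULT_BASELINE_WINDOWS, FeatureVector, GridSpec, prepare_cohort
from .tsp import indicator_matrix, ktsp_select

logger = logging.getLogger(__name__)

PRESETS = ("itlb1", "itlb2")


@dataclass(frozen=True)
class RunConfig:
    """Everything a training run needs, round-trippable through YAML."""

    grid: GridSpec = field(default_factory=GridSpec)
    baseline_windows: tuple[tuple[float, float], tuple[float, float]] | None = (
        DEFAULT_BASELINE_WINDOWS
    )
    preset: str = "itlb1"
    k_max: int = 10
    disjoint: bool = True
    cv_folds: int | None = None  # None → min(10, smallest class)
    lambda_rule: str = "min"
    fit_seed: int = 0
    n_boot: int = 2000
    eval_seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise PipelineError("config", f"unknown preset {self.preset!r}")

    # -- YAML round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        if self.baseline_windows is not None:
            d["baseline_windows"] = [list(w) for w in self.baseline_windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        if d.get("baseline_windows") is not None:
            d["baseline_windows"] = tuple(tuple(w) for w in d["baseline_windows"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    model: FittedModel
    train_scores: pd.DataFrame
    val_scores: pd.DataFrame
    confusion: ConfusionSummary
    roc: ROCResult
    wilcoxon_p: float
    config: RunConfig

    def metrics_dict(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "version": __version__,
            "preset": self.config.preset,
            "n_train": int(len(self.train_scores)),
            "n_validation": int(len(self.val_scores)),
            "pairs": [p.label() for p in self.model.pairs],
            "coefficients": self.model.coefficients.tolist(),
            "intercept": self.model.intercept,
            "penalty": self.model.penalty,
            "confusion": self.confusion.as_dict(),
            "metrics_percent": self.confusion.as_percent(),
            "auc": self.roc.auc,
            "auc_ci": [self.roc.ci_lo, self.roc.ci_hi],
            "wilcoxon_p": self.wilcoxon_p,
        }


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise TlbErrors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TlbError) and not isinstance(
                exc, PipelineError
            ):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_train(
    config: RunConfig,
    cohort: Cohort,
    outdir: str | Path | None = None,
) -> RunResult:
    """Train a preset model on a cohort and evaluate it.

    Stages: split (per preset) → preprocess all samples → kTSP pair
    selection on the training split → cross-validated lasso-logistic fit →
    score/classify training and validation samples → training confusion
    metrics, ROC/AUC and Wilcoxon rank-sum of the group scores.  Artifacts
    (model.json, scores.csv, metrics.json, run.log) are written when
    ``outdir`` is given.
    """
    with _stage("split"):
        if config.preset == "itlb1":
            train, val = train_validate_split(cohort)
        else:  # itlb2: all labeled samples train, nothing held out
            labeled = [s for s in cohort.sample_ids if s in cohort.labels]
            train = cohort.subset(labeled)
            val = cohort.subset([])
        train_labels = {s: cohort.labels[s] for s in train.sample_ids if s in cohort.labels}
        if len(set(train_labels.values())) < 2:
            raise PipelineError("split", "training split does not contain both classes")

    with _stage("prepare"):
        train_fv = prepare_cohort(train.thermograms, config.grid, config.baseline_windows)
        val_fv = prepare_cohort(val.thermograms, config.grid, config.baseline_windows)

    with _stage("ktsp_select"):
        train_fv_labeled = [fv for fv in train_fv if fv.sample_id in train_labels]
        pairs = ktsp_select(
            train_fv_labeled, train_labels, k_max=config.k_max, disjoint=config.disjoint
        )

    with _stage("fit"):
        pm = indicator_matrix(train_fv_labeled, pairs)
        model = fit(
            pm,
            train_labels,
            cv_folds=config.cv_folds,
            seed=config.fit_seed,
            lambda_rule=config.lambda_rule,
            grid_id=grid_hash(config.grid),
        )

    with _stage("score"):
        train_scores = make_score_table(score_features(model, train_fv), cohort.labels)
        val_scores = make_score_table(score_features(model, val_fv), cohort.labels)

    with _stage("evaluate"):
        train_eval = train_scores[train_scores["sample_id"].isin(train_labels)]
        confusion = confusion_metrics(train_eval)
        roc = roc_auc(train_eval, n_boot=config.n_boot, seed=config.eval_seed)
        s = train_eval["score"].to_numpy(float)
        y = train_eval["true"].to_numpy()
        _, wilcoxon_p = wilcoxon_rank_sum(
            s[y == model.negative_label], s[y == model.positive_label]
        )

    result = RunResult(
        model=model,
        train_scores=train_scores,
        val_scores=val_scores,
        confusion=confusion,
        roc=roc,
        wilcoxon_p=wilcoxon_p,
        config=config,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.to_json(outdir / "model.json")
        all_scores = pd.concat(
            [train_scores.assign(split="train"), val_scores.assign(split="validation")],
            ignore_index=True,
        )
        all_scores.to_csv(outdir / "scores.csv", index=False)
        (outdir / "metrics.json").write_text(
            json.dumps(result.metrics_dict(), indent=2)
        )
        (outdir / "run.log").write_text(
            "\n".join(
                [
                    f"tlbkit version: {__version__}",
                    f"config hash: {config.config_hash()}",
                    f"preset: {config.preset}",
                    f"fit seed: {config.fit_seed}",
                    f"eval seed: {config.eval_seed}",
                    f"n train: {len(train_scores)}",
                    f"n validation: {len(val_scores)}",
                    f"model pairs: {[p.label() for p in model.pairs]}",
                ]
            )
            + "\n"
        )
    return result


def run_predict(
    model: FittedModel | str | Path,
    cohort: Cohort,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score a cohort with a fitted model; no refitting.

    The cohort is preprocessed with the grid in ``config`` (default grid if
    omitted); the grid's hash must match the one recorded in the model, so
    a model is never silently applied to features on a different grid.
    """
    if not isinstance(model, FittedModel):
        model = FittedModel.from_json(model)
    config = config or RunConfig()
    gid = grid_hash(config.grid)
    if model.grid_id and model.grid_id != gid:
        raise PipelineError(
            "predict",
            f"model was trained on grid {model.grid_id} but the cohort is "
            f"prepared on grid {gid}",
        )
    with _stage("prepare"):
        fvs = prepare_cohort(cohort.thermograms, config.grid, config.baseline_windows)
    with _stage("score"):
        return make_score_table(score_features(model, fvs), cohort.labels or None)
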