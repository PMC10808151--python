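"""End-to-end orchestration: simulate (or load) -> probe filters -> CNV
calls -> horizon binarization -> the five prediction models -> evaluation,
collected into one deterministic master report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cnv as cnvmod
from .evaluate import EvalReport, evaluate_predictions
from .predictors import (
    FoldAssignment,
    ProbabilisticPrediction,
    apply_reject,
    cv_clinical_lr,
    encode_clinical_features,
    hyper_grid,
    integrated_stack,
    km_class_predictor,
    make_stratified_folds,
    nested_cv_svm,
)
from .preprocess import drop_failed_samples, run_probe_filters
from .simulate import CohortConfig, SimulatedCohort, simulate_cohort
from .survival import INDETERMINATE, SurvivalRecord, binarize_at_horizon

logger = logging.getLogger(__name__)

MODEL_TAGS = (
    "km_type", "km_subtype", "svm", "svm_reject", "clinical",
    "integrated", "integrated_reject",
)


@dataclass
class PipelineConfig:
    """All tunables of a full run; defaults follow the reference protocol
    (10x10 nested CV, top 10,000 variable CpGs, 60-month horizon, reject
    band [0.3, 0.7])."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    endpoint: str = "PFS"
    horizon: float = 60.0
    k_outer: int = 10
    k_inner: int = 10
    top_k: int = 10_000
    reject_low: float = 0.3
    reject_high: float = 0.7
    c_exponents: list[int] = field(default_factory=lambda: list(range(-5, 6)))
    gamma_exponents: list[int] = field(default_factory=lambda: list(range(-5, 6)))
    batch_mean_diff: float = 0.2
    batch_alpha: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cohort = CohortConfig(**cohort_raw)
        return cls(cohort=cohort, **raw)


def run_pipeline(config: PipelineConfig, cohort: SimulatedCohort | None = None) -> dict:
    """Run the full analysis and return the master report dictionary.

    Deterministic for a fixed config: rerunning with the same seed yields a
    byte-identical JSON serialization.
    """
    if cohort is None:
        cohort = simulate_cohort(config.cohort, seed=config.seed)

    detection_p = dict(
        zip(cohort.annotations["sample_id"], cohort.annotations["detection_p"])
    )
    beta = drop_failed_samples(cohort.beta, detection_p)
    beta, filter_report = run_probe_filters(
        beta, mean_diff=config.batch_mean_diff, alpha=config.batch_alpha
    )

    calls = cnvmod.call_table(cohort.cnv).set_index("sample_id")

    records = cohort.pfs if config.endpoint == "PFS" else cohort.os
    statuses = {
        s: binarize_at_horizon(records[s], config.horizon).status
        for s in beta.sample_ids
    }
    outcomes = {s: v for s, v in statuses.items() if v != INDETERMINATE}
    n_indeterminate = sum(1 for v in statuses.values() if v == INDETERMINATE)

    folds = make_stratified_folds(
        outcomes, k_outer=config.k_outer, k_inner=config.k_inner, seed=config.seed
    )

    ann = cohort.annotations.set_index("sample_id")
    features = encode_clinical_features(cohort.annotations.drop(
        columns=["gain_1q", "loss_6q", "cdkn2a_loss", "cdkn2b_loss"]
    ).merge(
        calls[["gain_1q", "loss_6q", "cdkn2a_loss", "cdkn2b_loss"]],
        left_on="sample_id", right_index=True, how="left",
    ))

    grid = hyper_grid(
        min(config.top_k, len(beta.cpg_ids)),
        c_exponents=config.c_exponents,
        gamma_exponents=config.gamma_exponents,
    )

    predictions: dict[str, list[ProbabilisticPrediction]] = {}

    # KM classifiers on molecular type / subtype, same outer folds
    for tag, column in (("km_type", "molecular_type"), ("km_subtype", "molecular_subtype")):
        preds = []
        for f in range(1, folds.k_outer + 1):
            train_ids = [s for s in folds.outer_train_ids(f) if s in outcomes]
            test_ids = [s for s in folds.outer_test_ids(f) if s in outcomes]
            preds.extend(
                km_class_predictor(
                    {s: ann.loc[s, column] for s in train_ids},
                    {s: records[s] for s in train_ids},
                    {s: ann.loc[s, column] for s in test_ids},
                    horizon=config.horizon,
                    outer_fold=f,
                    model_tag=tag,
                )
            )
        predictions[tag] = preds

    svm_result = nested_cv_svm(
        beta, outcomes, folds, top_k=config.top_k, grid=grid, model_tag="svm"
    )
    predictions["svm"] = svm_result.predictions
    predictions["svm_reject"] = apply_reject(
        svm_result.predictions, config.reject_low, config.reject_high,
        model_tag="svm_reject",
    )
    predictions["clinical"] = cv_clinical_lr(features, outcomes, folds)
    predictions["integrated"] = integrated_stack(svm_result, features, outcomes, folds)
    predictions["integrated_reject"] = apply_reject(
        predictions["integrated"], config.reject_low, config.reject_high,
        model_tag="integrated_reject",
    )

    reports = {}
    for tag in MODEL_TAGS:
        reports[tag] = evaluate_predictions(
            predictions[tag],
            outcomes,
            records=records,
            n_indeterminate=n_indeterminate,
            model_tag=tag,
        ).to_dict()

    report = {
        "schema_version": 1,
        "seed": config.seed,
        "endpoint": config.endpoint,
        "horizon_months": config.horizon,
        "n_samples": int(len(cohort.annotations)),
        "n_labeled": len(outcomes),
        "n_indeterminate": n_indeterminate,
        "filter_report": filter_report.to_dict(),
        "chosen_hyperparams": {
            str(f): {
                "kernel": hp.kernel,
                "C": hp.C,
                "gamma": hp.gamma,
            }
            for f, hp in svm_result.chosen_params.items()
        },
        "models": reports,
    }
    validate_report(report)
    return report


_REQUIRED_TOP = {
    "schema_version", "seed", "endpoint", "horizon_months", "n_samples",
    "n_labeled", "n_indeterminate", "filter_report", "chosen_hyperparams",
    "models",
}
_REQUIRED_MODEL = {
    "model_tag", "n_scored", "n_rejected", "n_indeterminate", "confusion",
    "accuracy", "balanced_accuracy", "coverage", "logrank_chi2", "logrank_p",
    "reliability",
}


def validate_report(report: dict) -> None:
    """Structural validation against the shipped master-report schema."""
    missing = _REQUIRED_TOP - set(report)
    if missing:
        raise ValueError(f"master report missing keys: {sorted(missing)}")
    for tag, model in report["models"].items():
        m_missing = _REQUIRED_MODEL - set(model)
        if m_missing:
            raise ValueError(f"model {tag}: missing keys {sorted(m_missing)}")
        cm = model["confusion"]
        if cm["tp"] + cm["fp"] + cm["fn"] + cm["tn"] != model["n_scored"]:
            raise ValueError(f"model {tag}: confusion counts do not reconcile")


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(report_to_json(report))


def predictions_to_frame(
    predictions: Mapping[str, list[ProbabilisticPrediction]]
) -> pd.DataFrame:
    rows = [
        {
            "sample_id": p.sample_id,
            "model_tag": p.model_tag,
            "score_relapse": p.score_relapse,
            "label": p.label,
            "outer_fold": p.outer_fold,
            "rejected": int(p.rejected),
        }
        for preds in predictions.values()
        for p in preds
    ]
    return pd.DataFrame(rows)
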