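"""Scoring of probabilistic predictions: confusion matrices, balanced
accuracy, KM separation of predicted groups, reliability, and the
dimensionality-saturation sweep.

RELAPSE is the positive class throughout; rejected and indeterminate
samples never enter confusion counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .predictors import FoldAssignment, NestedCVResult, ProbabilisticPrediction, nested_cv_svm
from .preprocess import BetaMatrix
from .survival import NED, RELAPSE, KMCurve, SurvivalRecord, km_fit, logrank

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    model_tag: str
    n_scored: int
    n_rejected: int
    n_indeterminate: int
    confusion: ConfusionMatrix
    accuracy: float
    balanced_accuracy: float | None
    coverage: float
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    reliability: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "n_scored": self.n_scored,
            "n_rejected": self.n_rejected,
            "n_indeterminate": self.n_indeterminate,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "fn": self.confusion.fn, "tn": self.confusion.tn,
            },
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "coverage": self.coverage,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "reliability": self.reliability,
        }


def confusion(
    predictions: Sequence[ProbabilisticPrediction], truth: Mapping[str, str]
) -> ConfusionMatrix:
    """Counts over non-rejected predictions; RELAPSE is positive."""
    cm = ConfusionMatrix()
    any_scored = False
    for p in predictions:
        if p.rejected or p.sample_id not in truth:
            continue
        any_scored = True
        actual = truth[p.sample_id]
        if p.label == RELAPSE and actual == RELAPSE:
            cm.tp += 1
        elif p.label == RELAPSE and actual == NED:
            cm.fp += 1
        elif p.label == NED and actual == RELAPSE:
            cm.fn += 1
        elif p.label == NED and actual == NED:
            cm.tn += 1
    if not any_scored:
        raise ValueError("no scored (non-rejected) predictions with truth labels")
    return cm


def accuracies(cm: ConfusionMatrix) -> tuple[float, float | None]:
    """(accuracy, balanced accuracy); balanced accuracy is the macro-average
    of the two class recalls and is None when a truth class is absent."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.n
    pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
    if pos == 0 or neg == 0:
        logger.warning("one truth class absent; balanced accuracy undefined")
        return acc, None
    return acc, 0.5 * (cm.tp / pos + cm.tn / neg)


def km_by_prediction(
    predictions: Sequence[ProbabilisticPrediction],
    records: Mapping[str, SurvivalRecord],
) -> tuple[dict[str, KMCurve], float, float]:
    """Kaplan-Meier curves of the full follow-up records stratified by the
    predicted label (non-rejected predictions only), with the log-rank test
    between the predicted groups."""
    kept = [p for p in predictions if not p.rejected and p.sample_id in records]
    labels = sorted({p.label for p in kept})
    if len(labels) < 2:
        raise ValueError("need at least two predicted classes for stratification")
    curves = {
        lab: km_fit([records[p.sample_id] for p in kept if p.label == lab])
        for lab in labels
    }
    chi2, p = logrank(
        [records[p.sample_id] for p in kept], [p.label for p in kept]
    )
    return curves, chi2, p


def reliability(
    predictions: Sequence[ProbabilisticPrediction],
    truth: Mapping[str, str],
    n_bins: int = 10,
) -> list[dict]:
    """Equal-width calibration bins on the relapse probability score.

    Empty bins are emitted with n = 0 so the bins always partition [0, 1].
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    scored = [p for p in predictions if not p.rejected and p.sample_id in truth]
    rows = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if b < n_bins - 1:
            members = [p for p in scored if lo <= p.score_relapse < hi]
        else:
            members = [p for p in scored if lo <= p.score_relapse <= hi]
        n = len(members)
        rows.append(
            {
                "bin_center": float((lo + hi) / 2),
                "mean_score": float(np.mean([p.score_relapse for p in members]))
                if n else None,
                "empirical_relapse_fraction": float(
                    np.mean([truth[p.sample_id] == RELAPSE for p in members])
                ) if n else None,
                "n": n,
            }
        )
    return rows


def evaluate_predictions(
    predictions: Sequence[ProbabilisticPrediction],
    truth: Mapping[str, str],
    records: Mapping[str, SurvivalRecord] | None = None,
    n_indeterminate: int = 0,
    model_tag: str | None = None,
    n_bins: int = 10,
) -> EvalReport:
    """Full evaluation bundle for one model's predictions."""
    tag = model_tag or (predictions[0].model_tag if predictions else "")
    n_rejected = sum(1 for p in predictions if p.rejected)
    cm = confusion(predictions, truth)
    acc, bacc = accuracies(cm)
    chi2 = pval = None
    if records is not None:
        try:
            _, chi2, pval = km_by_prediction(predictions, records)
        except ValueError as exc:
            logger.warning("KM stratification unavailable for %s: %s", tag, exc)
    n_scored = cm.n
    return EvalReport(
        model_tag=tag,
        n_scored=n_scored,
        n_rejected=n_rejected,
        n_indeterminate=n_indeterminate,
        confusion=cm,
        accuracy=acc,
        balanced_accuracy=bacc,
        coverage=n_scored / (n_scored + n_rejected) if (n_scored + n_rejected) else 0.0,
        logrank_chi2=chi2,
        logrank_p=pval,
        reliability=reliability(predictions, truth, n_bins=n_bins),
    )


def dimensionality_sweep(
    beta: BetaMatrix,
    outcomes: Mapping[str, str],
    folds: FoldAssignment,
    k_values: Sequence[int],
    grid=None,
) -> list[dict]:
    """Pooled inner log loss of the selected configuration at each feature
    count ``k`` (duplicates deduplicated); used to check saturation of the
    log-loss decline as dimensionality grows."""
    ks = sorted(set(int(k) for k in k_values))
    rows = []
    for k in ks:
        res = nested_cv_svm(beta, outcomes, folds, top_k=k, grid=grid)
        losses = list(res.inner_losses.values())
        rows.append({"k": k, "pooled_inner_log_loss": float(np.mean(losses))})
    return rows
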