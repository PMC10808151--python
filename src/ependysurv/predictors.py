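"""Five-year-PFS predictors evaluated on one shared nested-CV fold structure.

Four competing predictors plus their integration:

* ``km_class_predictor`` — Kaplan-Meier survivor fraction at the horizon per
  molecular type (or subtype) on the training folds, thresholded at 0.5;
* ``nested_cv_svm`` — SVM on the top-variable CpGs with hyperparameters
  chosen by pooled inner out-of-fold log loss in a nested cross-validation
  (dimension reduction inside each outer loop, so no leakage);
* ``clinical_lr`` — maximum-likelihood logistic regression on clinical risk
  factors and CNV statuses;
* ``integrated_stack`` — logistic model stacking the SVM's inner
  out-of-fold probability scores with the clinical/CNV covariates.

A reject option withholds predictions whose relapse probability falls in
the uncertain middle band (strictly between the low and high thresholds is
kept; scores at or inside [low, high] are rejected).
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import BetaMatrix, select_top_variable
from .survival import NED, RELAPSE, SurvivalRecord, km_at, km_fit

logger = logging.getLogger(__name__)

LINEAR = "LINEAR"
RBF = "RBF"


@dataclass(frozen=True)
class HyperParams:
    kernel: str
    C: float
    gamma: float | None = None  # ignored for LINEAR


@dataclass
class FoldAssignment:
    """Class-balanced nested fold structure keyed by sample id."""

    outer_fold: dict[str, int]
    inner_folds: dict[int, dict[str, int]]
    seed: int

    @property
    def k_outer(self) -> int:
        return max(self.outer_fold.values())

    def outer_test_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.outer_fold.items() if f == fold)

    def outer_train_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.outer_fold.items() if f != fold)


@dataclass
class ProbabilisticPrediction:
    sample_id: str
    score_relapse: float
    label: str
    outer_fold: int
    rejected: bool = False
    model_tag: str = ""


@dataclass
class NestedCVResult:
    predictions: list[ProbabilisticPrediction]
    inner_scores: dict[int, dict[str, float]]  # outer fold -> train sid -> OOF score
    chosen_params: dict[int, HyperParams]
    inner_losses: dict[int, float]  # pooled inner log loss of the chosen config
    # sha256 over (selected CpG ids, training matrix bytes, training labels)
    # per outer fold: a mechanical anti-leakage witness — mutating outer-test
    # data must leave every hash unchanged
    train_input_hashes: dict[int, str] = field(default_factory=dict)


def make_stratified_folds(
    labels: Mapping[str, str],
    k_outer: int = 10,
    k_inner: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Stratified outer partition plus stratified inner partitions per outer
    training set; per-fold class counts deviate from the overall proportions
    by at most one sample per class. Deterministic given the seed."""
    ids = sorted(labels)
    y = np.array([labels[s] for s in ids])
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_outer:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k_outer={k_outer}; "
            "lower k_outer"
        )
    outer: dict[str, int] = {}
    if k_outer == 1:
        outer = {s: 1 for s in ids}
    else:
        skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed % 2**31)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), y), start=1):
            for i in test_idx:
                outer[ids[i]] = f
    inner: dict[int, dict[str, int]] = {}
    for f in range(1, k_outer + 1):
        train_ids = sorted(s for s in ids if outer[s] != f) if k_outer > 1 else ids
        ty = np.array([labels[s] for s in train_ids])
        _, tcounts = np.unique(ty, return_counts=True)
        ki = min(k_inner, int(tcounts.min()))
        if ki < k_inner:
            logger.warning(
                "outer fold %d: smallest class %d < k_inner=%d, using %d",
                f, int(tcounts.min()), k_inner, ki,
            )
        if ki < 2:
            raise ValueError("cannot build inner folds with < 2 splits")
        iskf = StratifiedKFold(
            n_splits=ki, shuffle=True, random_state=(seed * 31 + f) % 2**31
        )
        fold_of: dict[str, int] = {}
        for j, (_, val_idx) in enumerate(
            iskf.split(np.zeros(len(train_ids)), ty), start=1
        ):
            for i in val_idx:
                fold_of[train_ids[i]] = j
        inner[f] = fold_of
    return FoldAssignment(outer_fold=outer, inner_folds=inner, seed=seed)


def hyper_grid(
    n_features: int,
    c_exponents: Sequence[int] = tuple(range(-5, 6)),
    gamma_exponents: Sequence[int] = tuple(range(-5, 6)),
) -> list[HyperParams]:
    """Linear C grid plus RBF C x gamma grid; the gamma base is
    1/sqrt(n_features). Default exponents -5..5 give 11 + 121 = 132 configs."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    gamma_base = 1.0 / math.sqrt(n_features)
    grid = [HyperParams(LINEAR, 2.0**e) for e in c_exponents]
    grid += [
        HyperParams(RBF, 2.0**e, gamma=(2.0**g) * gamma_base)
        for e in c_exponents
        for g in gamma_exponents
    ]
    return grid


def log_loss(scores, binary_labels, eps: float = 1e-15) -> float:
    """-mean[y ln p + (1-y) ln(1-p)] with p clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(scores, dtype=float), eps, 1 - eps)
    y = np.asarray(binary_labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("scores and labels must align")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Monotone sigmoid calibration of decision values, fitted on training
    data only (Platt-type; a lightly regularized logistic fit keeps the map
    finite under separation)."""
    lr = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000)
    lr.fit(decision.reshape(-1, 1), y)
    return lr


def _platt_scores(platt: LogisticRegression, decision: np.ndarray) -> np.ndarray:
    return platt.predict_proba(decision.reshape(-1, 1))[:, 1]


def _kernel_matrices(X: np.ndarray, X2: np.ndarray | None = None):
    """Gram matrix and squared-distance matrix (rows of X2 vs rows of X)."""
    if X2 is None:
        X2 = X
    G = X2 @ X.T
    sq1 = np.einsum("ij,ij->i", X, X)
    sq2 = np.einsum("ij,ij->i", X2, X2)
    D = np.maximum(sq2[:, None] + sq1[None, :] - 2.0 * G, 0.0)
    return G, D


def _kernel(params: HyperParams, G: np.ndarray, D: np.ndarray) -> np.ndarray:
    if params.kernel == LINEAR:
        return G
    return np.exp(-params.gamma * D)


def outcomes_to_binary(outcomes: Mapping[str, str]) -> dict[str, int]:
    bad = {v for v in outcomes.values() if v not in (RELAPSE, NED)}
    if bad:
        raise ValueError(f"non-binary outcomes present: {sorted(bad)}")
    return {s: int(v == RELAPSE) for s, v in outcomes.items()}


def nested_cv_svm(
    beta: BetaMatrix,
    outcomes: Mapping[str, str],
    folds: FoldAssignment,
    top_k: int = 10_000,
    grid: Sequence[HyperParams] | None = None,
    model_tag: str = "svm",
) -> NestedCVResult:
    """Nested-CV SVM with per-outer-loop dimension reduction.

    For each outer fold the ``top_k`` most variable CpGs are recomputed on
    the outer-training samples only. Every grid configuration is scored by
    its pooled inner out-of-fold log loss; the minimizing configuration
    (first in grid order on ties) is refit on the full outer-training set.
    Probability scores come from a Platt-type sigmoid on training decision
    values. Kernels are precomputed once per outer fold, so the grid search
    costs one SVM solve per configuration and inner fold.
    """
    y_bin = outcomes_to_binary(outcomes)
    labeled = sorted(set(y_bin) & set(folds.outer_fold))
    if top_k > len(beta.cpg_ids):
        logger.warning(
            "top_k=%d exceeds available CpGs (%d); clamping", top_k, len(beta.cpg_ids)
        )
        top_k = len(beta.cpg_ids)

    predictions: list[ProbabilisticPrediction] = []
    inner_scores: dict[int, dict[str, float]] = {}
    chosen: dict[int, HyperParams] = {}
    chosen_losses: dict[int, float] = {}
    train_hashes: dict[int, str] = {}

    for f in range(1, folds.k_outer + 1):
        train_ids = [s for s in folds.outer_train_ids(f) if s in y_bin]
        test_ids = [s for s in folds.outer_test_ids(f) if s in y_bin]
        if folds.k_outer == 1:
            train_ids, test_ids = labeled, []
        top = select_top_variable(beta.subset_samples(train_ids), top_k)
        X_tr = np.ascontiguousarray(beta.values.loc[train_ids, top].to_numpy())
        y_tr = np.array([y_bin[s] for s in train_ids])
        digest = hashlib.sha256()
        digest.update("\n".join(top).encode())
        digest.update(X_tr.tobytes())
        digest.update(y_tr.tobytes())
        train_hashes[f] = digest.hexdigest()
        G, D = _kernel_matrices(X_tr)

        inner_map = folds.inner_folds[f]
        inner_ids = sorted(inner_map)
        n_inner = max(inner_map.values())
        idx_of = {s: i for i, s in enumerate(train_ids)}

        if grid is None:
            grid_f = hyper_grid(len(top))
        else:
            grid_f = list(grid)

        best = None  # (loss, grid position, params, oof scores)
        for pos, params in enumerate(grid_f):
            K = _kernel(params, G, D)
            oof = np.full(len(train_ids), np.nan)
            for j in range(1, n_inner + 1):
                val_ids = [s for s in inner_ids if inner_map[s] == j]
                fit_ids = [s for s in inner_ids if inner_map[s] != j]
                fit_idx = np.array([idx_of[s] for s in fit_ids])
                val_idx = np.array([idx_of[s] for s in val_ids])
                if len(np.unique(y_tr[fit_idx])) < 2:
                    continue
                clf = SVC(kernel="precomputed", C=params.C)
                clf.fit(K[np.ix_(fit_idx, fit_idx)], y_tr[fit_idx])
                d_fit = clf.decision_function(K[np.ix_(fit_idx, fit_idx)])
                platt = _fit_platt(d_fit, y_tr[fit_idx])
                d_val = clf.decision_function(K[np.ix_(val_idx, fit_idx)])
                oof[val_idx] = _platt_scores(platt, d_val)
            mask = ~np.isnan(oof)
            loss = log_loss(oof[mask], y_tr[mask])
            if best is None or loss < best[0]:
                best = (loss, pos, params, oof.copy())
        loss, _, params, oof = best
        chosen[f] = params
        chosen_losses[f] = loss
        inner_scores[f] = {
            s: float(oof[idx_of[s]])
            for s in train_ids
            if not np.isnan(oof[idx_of[s]])
        }

        # final refit on the full outer-training set
        K = _kernel(params, G, D)
        clf = SVC(kernel="precomputed", C=params.C)
        clf.fit(K, y_tr)
        platt = _fit_platt(clf.decision_function(K), y_tr)
        if test_ids:
            X_te = beta.values.loc[test_ids, top].to_numpy()
            G_c, D_c = _kernel_matrices(X_tr, X_te)
            K_c = G_c if params.kernel == LINEAR else np.exp(-params.gamma * D_c)
            scores = _platt_scores(platt, clf.decision_function(K_c))
            for s, p in zip(test_ids, scores):
                predictions.append(
                    ProbabilisticPrediction(
                        sample_id=s,
                        score_relapse=float(p),
                        label=RELAPSE if p >= 0.5 else NED,
                        outer_fold=f,
                        model_tag=model_tag,
                    )
                )
    return NestedCVResult(
        predictions=predictions,
        inner_scores=inner_scores,
        chosen_params=chosen,
        inner_losses=chosen_losses,
        train_input_hashes=train_hashes,
    )


def apply_reject(
    predictions: Sequence[ProbabilisticPrediction],
    low: float = 0.3,
    high: float = 0.7,
    model_tag: str | None = None,
) -> list[ProbabilisticPrediction]:
    """Keep only confident predictions: score strictly below ``low`` or
    strictly above ``high``; scores at the boundaries are rejected."""
    out = []
    for p in predictions:
        kept = p.score_relapse < low or p.score_relapse > high
        out.append(
            replace(p, rejected=not kept, model_tag=model_tag or p.model_tag)
        )
    return out


def coverage(predictions: Sequence[ProbabilisticPrediction]) -> float:
    if not predictions:
        return 0.0
    kept = sum(1 for p in predictions if not p.rejected)
    return kept / len(predictions)


def km_class_predictor(
    train_groups: Mapping[str, str],
    train_records: Mapping[str, SurvivalRecord],
    test_groups: Mapping[str, str],
    horizon: float = 60.0,
    outer_fold: int = 0,
    model_tag: str = "km_type",
) -> list[ProbabilisticPrediction]:
    """Kaplan-Meier classifier: estimate the survivor fraction at the
    horizon per training (sub)type and predict NED when it is >= 0.5.

    A test (sub)type unseen in training — or whose training records contain
    no event and no follow-up reaching the horizon — falls back to the
    pooled all-training-samples estimate (logged).
    """
    if not train_records:
        raise ValueError("empty training set")
    pooled = km_fit(list(train_records.values()))
    pooled_s = km_at(pooled, horizon)
    group_s: dict[str, float] = {}
    for g in sorted(set(train_groups.values())):
        recs = [train_records[s] for s in train_records if train_groups[s] == g]
        curve = km_fit(recs)
        informative = curve.event_times.size > 0 or curve.max_observed_time >= horizon
        if informative:
            group_s[g] = km_at(curve, horizon)
    preds = []
    for s in sorted(test_groups):
        g = test_groups[s]
        if g in group_s:
            s_hat = group_s[g]
        else:
            logger.info("group %r falls back to pooled KM estimate", g)
            s_hat = pooled_s
        preds.append(
            ProbabilisticPrediction(
                sample_id=s,
                score_relapse=1.0 - s_hat,
                label=NED if s_hat >= 0.5 else RELAPSE,
                outer_fold=outer_fold,
                model_tag=model_tag,
            )
        )
    return preds


# --- logistic models -------------------------------------------------------

CLINICAL_COLUMNS = [
    "age_4_18", "age_gt18", "sex_male", "resection_str",
    "gain_1q", "loss_6q", "cdkn2a_loss", "cdkn2b_loss",
]


def encode_clinical_features(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot clinical/CNV design matrix indexed by sample id.

    Reference levels: age < 4 years, female sex, gross-total resection,
    no CNV lesion. Missing inputs propagate as NaN so complete-case
    filtering can count them.
    """
    out = pd.DataFrame(index=df["sample_id"].astype(str))
    age = df["age_group"].to_numpy()
    out["age_4_18"] = [
        np.nan if pd.isna(a) else float(a == "4-18") for a in age
    ]
    out["age_gt18"] = [np.nan if pd.isna(a) else float(a == ">18") for a in age]
    out["sex_male"] = [
        np.nan if pd.isna(s) else float(s == "male") for s in df["sex"]
    ]
    out["resection_str"] = [
        np.nan if pd.isna(r) else float(r == "STR") for r in df["resection"]
    ]
    for col in ("gain_1q", "loss_6q", "cdkn2a_loss", "cdkn2b_loss"):
        out[col] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    return out


@dataclass
class LogisticModel:
    """Fitted logistic model over named covariates.

    ``converged`` is False when the maximum-likelihood fit failed (for
    example under perfect separation), in which case coefficients come from
    a penalized fallback and predictions are still emitted.
    """

    columns: list[str]
    coef: np.ndarray  # intercept first
    converged: bool
    n_train: int
    n_dropped_incomplete: int
    dropped_constant: list[str] = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.columns].to_numpy(dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(
    features: pd.DataFrame, y: np.ndarray, n_dropped_incomplete: int = 0
) -> LogisticModel:
    """Maximum-likelihood logistic fit with a penalized fallback.

    Zero-variance covariates are dropped with a warning. On perfect
    separation or non-convergence of the ML fit, an L2-penalized fit
    (flagged ``converged=False``) supplies the coefficients.
    """
    import statsmodels.api as sm

    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    keep, dropped = [], []
    for j, c in enumerate(cols):
        (keep if np.ptp(X[:, j]) > 0 else dropped).append((j, c))
    if dropped:
        logger.warning(
            "dropping zero-variance covariate(s): %s", [c for _, c in dropped]
        )
    keep_idx = [j for j, _ in keep]
    keep_cols = [c for _, c in keep]
    Xk = X[:, keep_idx]
    converged = False
    coef = None
    if len(np.unique(y)) < 2:
        # intercept-only, class rate collapses to 0/1 -> clip
        rate = float(np.clip(np.mean(y), 1e-6, 1 - 1e-6))
        coef = np.zeros(len(keep_cols) + 1)
        coef[0] = math.log(rate / (1 - rate))
        converged = True
    else:
        design = sm.add_constant(Xk, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(
                np.abs(res.params) < 1e4
            ):
                coef = np.asarray(res.params, dtype=float)
                converged = True
        except Exception:  # separation and numeric failures
            pass
        if coef is None:
            logger.warning("ML logistic fit failed; using penalized fallback")
            lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
            if Xk.shape[1] == 0:
                rate = float(np.clip(np.mean(y), 1e-6, 1 - 1e-6))
                coef = np.array([math.log(rate / (1 - rate))])
            else:
                lr.fit(Xk, y)
                coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return LogisticModel(
        columns=keep_cols,
        coef=coef,
        converged=converged,
        n_train=len(y),
        n_dropped_incomplete=n_dropped_incomplete,
        dropped_constant=[c for _, c in dropped],
    )


def clinical_lr(
    train_features: pd.DataFrame, outcomes: Mapping[str, str]
) -> LogisticModel:
    """Logistic model of relapse on clinical risk factors and CNV lesions.

    Complete cases only: training samples missing any covariate are dropped
    and counted in the returned model.
    """
    ids = [s for s in train_features.index if s in outcomes]
    feats = train_features.loc[ids, CLINICAL_COLUMNS]
    complete = feats.dropna()
    n_dropped = len(feats) - len(complete)
    if complete.empty:
        raise ValueError("no complete-case training samples")
    y = np.array([outcomes[s] == RELAPSE for s in complete.index], dtype=float)
    return fit_logistic(complete, y, n_dropped_incomplete=n_dropped)


def predict_lr(
    model: LogisticModel,
    features: pd.DataFrame,
    outer_fold: int = 0,
    model_tag: str = "clinical",
) -> list[ProbabilisticPrediction]:
    complete = features[CLINICAL_COLUMNS].dropna() \
        if set(CLINICAL_COLUMNS).issubset(features.columns) else features.dropna()
    scores = model.predict(complete)
    return [
        ProbabilisticPrediction(
            sample_id=str(s),
            score_relapse=float(p),
            label=RELAPSE if p >= 0.5 else NED,
            outer_fold=outer_fold,
            model_tag=model_tag,
        )
        for s, p in zip(complete.index, scores)
    ]


def cv_clinical_lr(
    features: pd.DataFrame,
    outcomes: Mapping[str, str],
    folds: FoldAssignment,
    model_tag: str = "clinical",
) -> list[ProbabilisticPrediction]:
    """Clinical/CNV logistic model evaluated on the shared outer folds."""
    predictions: list[ProbabilisticPrediction] = []
    for f in range(1, folds.k_outer + 1):
        train_ids = [s for s in folds.outer_train_ids(f) if s in outcomes]
        test_ids = [s for s in folds.outer_test_ids(f) if s in outcomes]
        model = clinical_lr(features.loc[features.index.isin(train_ids)], outcomes)
        test_feats = features.loc[features.index.isin(test_ids)]
        predictions.extend(
            predict_lr(model, test_feats, outer_fold=f, model_tag=model_tag)
        )
    return predictions


def integrated_stack(
    svm_result: NestedCVResult,
    features: pd.DataFrame,
    outcomes: Mapping[str, str],
    folds: FoldAssignment,
    model_tag: str = "integrated",
) -> list[ProbabilisticPrediction]:
    """Stacked model: per outer fold, a logistic regression on the SVM's
    inner out-of-fold probability scores plus the clinical/CNV covariates,
    applied to the outer-test samples' outer-fold SVM scores.

    Complete-case analysis; outer-test samples without an SVM score are
    skipped and reported via a log message.
    """
    outer_scores = {
        p.sample_id: p.score_relapse for p in svm_result.predictions
    }
    predictions: list[ProbabilisticPrediction] = []
    for f in range(1, folds.k_outer + 1):
        inner = svm_result.inner_scores.get(f, {})
        train_ids = [
            s for s in folds.outer_train_ids(f)
            if s in outcomes and s in inner and s in features.index
        ]
        feats = features.loc[train_ids, CLINICAL_COLUMNS].copy()
        feats.insert(0, "svm_score", [inner[s] for s in train_ids])
        complete = feats.dropna()
        if complete.empty:
            raise ValueError(f"outer fold {f}: no complete-case training samples")
        y = np.array([outcomes[s] == RELAPSE for s in complete.index], dtype=float)
        model = fit_logistic(
            complete, y, n_dropped_incomplete=len(feats) - len(complete)
        )
        test_ids = [s for s in folds.outer_test_ids(f) if s in outcomes]
        skipped = [s for s in test_ids if s not in outer_scores]
        if skipped:
            logger.warning(
                "outer fold %d: %d test sample(s) lack an SVM score; skipped",
                f, len(skipped),
            )
        test_ids = [s for s in test_ids if s in outer_scores and s in features.index]
        tfeats = features.loc[test_ids, CLINICAL_COLUMNS].copy()
        tfeats.insert(0, "svm_score", [outer_scores[s] for s in test_ids])
        tcomplete = tfeats.dropna()
        if tcomplete.empty:
            continue
        scores = model.predict(tcomplete)
        for s, p in zip(tcomplete.index, scores):
            predictions.append(
                ProbabilisticPrediction(
                    sample_id=str(s),
                    score_relapse=float(p),
                    label=RELAPSE if p >= 0.5 else NED,
                    outer_fold=f,
                    model_tag=model_tag,
                )
            )
    return predictions
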