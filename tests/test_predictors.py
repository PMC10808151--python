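"""Fold construction, hyperparameter grid, log loss, nested-CV SVM with
leakage guards, the reject option, KM classifier and logistic models."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import labeled_outcomes, reduced_grid
from ependysurv.predictors import (
    CLINICAL_COLUMNS,
    FoldAssignment,
    HyperParams,
    ProbabilisticPrediction,
    apply_reject,
    clinical_lr,
    coverage,
    cv_clinical_lr,
    encode_clinical_features,
    fit_logistic,
    hyper_grid,
    integrated_stack,
    km_class_predictor,
    log_loss,
    make_stratified_folds,
    nested_cv_svm,
)
from ependysurv.preprocess import BetaMatrix
from ependysurv.survival import NED, RELAPSE, SurvivalRecord


class TestMakeStratifiedFolds:
    def test_balanced_10_10_into_5_folds(self):
        labels = {f"s{i:02d}": RELAPSE if i < 10 else NED for i in range(20)}
        folds = make_stratified_folds(labels, k_outer=5, k_inner=2, seed=0)
        for f in range(1, 6):
            test = folds.outer_test_ids(f)
            assert len(test) == 4
            assert sum(labels[s] == RELAPSE for s in test) == 2

    def test_single_fold_holds_all(self):
        labels = {f"s{i}": RELAPSE if i % 2 else NED for i in range(10)}
        folds = make_stratified_folds(labels, k_outer=1, k_inner=2, seed=0)
        assert set(folds.outer_fold.values()) == {1}

    def test_deterministic_given_seed(self):
        labels = {f"s{i:02d}": RELAPSE if i % 3 == 0 else NED for i in range(30)}
        a = make_stratified_folds(labels, 5, 3, seed=7)
        b = make_stratified_folds(labels, 5, 3, seed=7)
        assert a.outer_fold == b.outer_fold
        assert a.inner_folds == b.inner_folds

    def test_partition_and_class_balance_invariants(self):
        labels = {f"s{i:03d}": RELAPSE if i < 37 else NED for i in range(100)}
        folds = make_stratified_folds(labels, k_outer=10, k_inner=5, seed=1)
        seen = [s for f in range(1, 11) for s in folds.outer_test_ids(f)]
        assert sorted(seen) == sorted(labels)
        per_fold_pos = [
            sum(labels[s] == RELAPSE for s in folds.outer_test_ids(f))
            for f in range(1, 11)
        ]
        assert max(per_fold_pos) - min(per_fold_pos) <= 1
        for f in range(1, 11):
            inner = folds.inner_folds[f]
            assert sorted(inner) == folds.outer_train_ids(f)

    def test_small_class_rejected_with_guidance(self):
        labels = {f"s{i}": RELAPSE if i < 3 else NED for i in range(20)}
        with pytest.raises(ValueError, match="lower k"):
            make_stratified_folds(labels, k_outer=5, k_inner=2, seed=0)


class TestHyperGrid:
    def test_full_grid_size_and_gamma_base(self):
        grid = hyper_grid(10_000)
        assert len(grid) == 132
        assert sum(g.kernel == "LINEAR" for g in grid) == 11
        rbf_gammas = sorted({g.gamma for g in grid if g.kernel == "RBF"})
        assert min(rbf_gammas) == pytest.approx(2**-5 * 0.01)
        assert max(rbf_gammas) == pytest.approx(2**5 * 0.01)

    def test_gamma_base_one_feature(self):
        grid = hyper_grid(1)
        gammas = {g.gamma for g in grid if g.kernel == "RBF"}
        assert 1.0 in gammas  # 2^0 * 1/sqrt(1)

    def test_c_range(self):
        grid = hyper_grid(100)
        cs = sorted({g.C for g in grid})
        assert cs[0] == 2**-5 and cs[-1] == 2**5


class TestLogLoss:
    def test_perfect_scores_zero(self):
        assert log_loss([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_uninformative_half_is_ln2(self):
        assert log_loss([0.5] * 4, [1, 0, 1, 0]) == pytest.approx(math.log(2))

    def test_hand_example(self):
        expected = -(math.log(0.8) + math.log(0.6)) / 2
        assert log_loss([0.8, 0.4], [1, 0]) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.3670, abs=1e-4)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            log_loss([0.5], [1, 0])


@pytest.fixture(scope="module")
def signal_setup():
    """Injected-signal cohort, preprocessed, with shared folds."""
    from ependysurv.preprocess import run_probe_filters
    from ependysurv.simulate import CohortConfig, inject_known_signal, simulate_cohort

    cfg = CohortConfig(
        n_samples=300, n_cpgs=1500, n_informative=300, n_batch_cpgs=75, seed=13
    )
    cohort = inject_known_signal(simulate_cohort(cfg), effect=0.4)
    beta, _ = run_probe_filters(cohort.beta)
    outcomes = labeled_outcomes(cohort, beta.sample_ids)
    folds = make_stratified_folds(outcomes, k_outer=3, k_inner=3, seed=13)
    return cohort, beta, outcomes, folds


class TestNestedCVSVM:
    def test_learns_injected_signal(self, signal_setup):
        cohort, beta, outcomes, folds = signal_setup
        res = nested_cv_svm(
            beta, outcomes, folds, top_k=400, grid=reduced_grid(400)
        )
        scored = {p.sample_id: p for p in res.predictions}
        assert sorted(scored) == sorted(outcomes)
        correct = sum(
            (p.score_relapse >= 0.5) == (outcomes[s] == RELAPSE)
            for s, p in scored.items()
        )
        assert correct / len(scored) > 0.85

    def test_oracle_refit_on_truth_block_agrees(self, signal_setup):
        """Independent oracle: an SVM refit on the truth-labeled signal block
        alone separates the classes, confirming the signal the nested CV is
        expected to find."""
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC

        cohort, beta, outcomes, _ = signal_setup
        block = [
            c for c in cohort.truth["signal_cpg_ids"] if c in set(beta.cpg_ids)
        ]
        ids = sorted(outcomes)
        X = beta.values.loc[ids, block].to_numpy()
        y = np.array([outcomes[s] == RELAPSE for s in ids])
        acc = cross_val_score(SVC(), X, y, cv=3).mean()
        assert acc > 0.9

    def test_inner_scores_cover_training_samples(self, signal_setup):
        _, beta, outcomes, folds = signal_setup
        res = nested_cv_svm(beta, outcomes, folds, top_k=200, grid=reduced_grid(200))
        for f in range(1, folds.k_outer + 1):
            train = [s for s in folds.outer_train_ids(f) if s in outcomes]
            assert sorted(res.inner_scores[f]) == sorted(train)
            assert all(0 <= v <= 1 for v in res.inner_scores[f].values())

    def test_leakage_guard_mutating_test_data_changes_nothing(self, signal_setup):
        """Mutating outer-test labels and features must leave every fitted
        component untouched: chosen hyperparameters and inner out-of-fold
        scores are bit-identical."""
        _, beta, outcomes, folds = signal_setup
        grid = reduced_grid(200)
        base = nested_cv_svm(beta, outcomes, folds, top_k=200, grid=grid)

        test_ids = folds.outer_test_ids(1)
        flipped = dict(outcomes)
        for s in test_ids:
            if s in flipped:
                flipped[s] = RELAPSE if flipped[s] == NED else NED
        values = beta.values.copy()
        rng = np.random.default_rng(0)
        values.loc[test_ids] = rng.uniform(size=values.loc[test_ids].shape)
        mutated_beta = BetaMatrix(values=values, platform=beta.platform)

        mutated = nested_cv_svm(mutated_beta, flipped, folds, top_k=200, grid=grid)
        assert mutated.chosen_params[1] == base.chosen_params[1]
        assert mutated.inner_scores[1] == base.inner_scores[1]
        assert mutated.inner_losses[1] == base.inner_losses[1]

    def test_sentinel_cpg_in_test_folds_does_not_leak(self, signal_setup):
        """A CpG made perfectly informative only in outer-test samples must
        not change chosen hyperparameters or training-fold scores."""
        _, beta, outcomes, folds = signal_setup
        grid = reduced_grid(200)
        base = nested_cv_svm(beta, outcomes, folds, top_k=200, grid=grid)
        values = beta.values.copy()
        test_ids = [s for s in folds.outer_test_ids(1) if s in outcomes]
        sentinel = values.columns[0]
        values.loc[test_ids, sentinel] = [
            1.0 if outcomes[s] == RELAPSE else 0.0 for s in test_ids
        ]
        leaky = nested_cv_svm(
            BetaMatrix(values=values, platform=beta.platform),
            outcomes, folds, top_k=200, grid=grid,
        )
        assert leaky.chosen_params[1] == base.chosen_params[1]
        assert leaky.inner_scores[1] == base.inner_scores[1]

    def test_fold_invariance_under_sample_shuffle(self, signal_setup):
        """With the fold assignment fixed by sample id, shuffling the row
        order of the beta matrix leaves all out-of-fold scores unchanged."""
        _, beta, outcomes, folds = signal_setup
        grid = reduced_grid(200)
        base = nested_cv_svm(beta, outcomes, folds, top_k=200, grid=grid)
        rng = np.random.default_rng(5)
        order = list(rng.permutation(beta.sample_ids))
        shuffled = BetaMatrix(
            values=beta.values.loc[order], platform=beta.platform.loc[order]
        )
        moved = nested_cv_svm(shuffled, outcomes, folds, top_k=200, grid=grid)
        base_scores = {p.sample_id: p.score_relapse for p in base.predictions}
        moved_scores = {p.sample_id: p.score_relapse for p in moved.predictions}
        assert base_scores.keys() == moved_scores.keys()
        for s in base_scores:
            assert moved_scores[s] == pytest.approx(base_scores[s], abs=1e-9)

    def test_top_k_clamped_with_warning(self, signal_setup, caplog):
        _, beta, outcomes, folds = signal_setup
        import logging

        with caplog.at_level(logging.WARNING):
            res = nested_cv_svm(
                beta, outcomes, folds, top_k=10**6, grid=reduced_grid(100)
            )
        assert "clamping" in caplog.text
        assert len(res.predictions) == len(outcomes)

    def test_non_binary_outcomes_rejected(self, signal_setup):
        _, beta, outcomes, folds = signal_setup
        bad = dict(outcomes)
        bad[next(iter(bad))] = "INDETERMINATE"
        with pytest.raises(ValueError, match="non-binary"):
            nested_cv_svm(beta, bad, folds, top_k=50, grid=reduced_grid(50))


class TestApplyReject:
    @pytest.mark.parametrize(
        "score,kept",
        [(0.5, False), (0.95, True), (0.3, False), (0.7, False),
         (0.29, True), (0.71, True), (0.0, True), (1.0, True)],
    )
    def test_strict_boundaries(self, score, kept):
        pred = ProbabilisticPrediction("s0", score, RELAPSE, 1)
        out = apply_reject([pred])
        assert out[0].rejected is (not kept)

    def test_coverage_reported(self):
        preds = [
            ProbabilisticPrediction(f"s{i}", s, RELAPSE, 1)
            for i, s in enumerate([0.1, 0.5, 0.9, 0.65])
        ]
        out = apply_reject(preds)
        assert coverage(out) == pytest.approx(0.5)


class TestKMClassPredictor:
    def _records(self, spec):
        """spec: list of (group, time, event)."""
        groups = {f"s{i}": g for i, (g, _, _) in enumerate(spec)}
        recs = {
            f"s{i}": SurvivalRecord(t, e) for i, (_, t, e) in enumerate(spec)
        }
        return groups, recs

    def test_low_survival_type_predicts_relapse(self):
        # type X: 7/10 events before 60 -> S(60) < 0.5
        spec = [("X", 10 + i, 1) for i in range(7)] + [("X", 100, 0)] * 3
        groups, recs = self._records(spec)
        preds = km_class_predictor(groups, recs, {"t1": "X", "t2": "X"})
        assert all(p.label == RELAPSE for p in preds)
        assert all(p.score_relapse > 0.5 for p in preds)

    def test_all_censored_past_horizon_predicts_ned(self):
        spec = [("X", 80, 0)] * 5
        groups, recs = self._records(spec)
        preds = km_class_predictor(groups, recs, {"t1": "X"})
        assert preds[0].label == NED
        assert preds[0].score_relapse == pytest.approx(0.0)

    def test_unseen_type_uses_pooled_fallback(self):
        """An unseen test type falls back to the all-training KM estimate;
        oracle: the pooled product-limit value at the horizon."""
        from ependysurv.survival import km_at, km_fit

        spec = [("X", 20, 1)] * 6 + [("X", 100, 0)] * 4
        groups, recs = self._records(spec)
        pooled_s = km_at(km_fit(list(recs.values())), 60)
        preds = km_class_predictor(groups, recs, {"t1": "UNSEEN"})
        assert preds[0].score_relapse == pytest.approx(1 - pooled_s)
        assert pooled_s < 0.5 and preds[0].label == RELAPSE

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            km_class_predictor({}, {}, {"t": "X"})

    def test_tie_at_half_labels_ned(self):
        # exactly S(60) = 0.5: 1 event of 2 at t=30
        spec = [("X", 30, 1), ("X", 100, 0)]
        groups, recs = self._records(spec)
        preds = km_class_predictor(groups, recs, {"t1": "X"})
        assert preds[0].score_relapse == pytest.approx(0.5)
        assert preds[0].label == NED

    def test_bayes_assignment_on_separated_types(self, small_cohort):
        """Types with well-separated survival get the Bayes label: relapse
        iff the type's true survivor fraction at 60 months is below 0.5."""
        import math

        cfg = small_cohort.config
        groups = dict(
            zip(small_cohort.annotations["sample_id"],
                small_cohort.annotations["molecular_type"])
        )
        preds = km_class_predictor(groups, small_cohort.pfs, groups)
        # restrict to abundant types whose config S(60) is far from 0.5
        counts = small_cohort.annotations["molecular_type"].value_counts()
        for p in preds:
            t = groups[p.sample_id]
            s_true = cfg.five_year_pfs[t]
            if counts[t] >= 30 and abs(s_true - 0.5) > 0.15:
                assert p.label == (RELAPSE if s_true < 0.5 else NED)


class TestLogisticModels:
    def test_intercept_only_class_rate(self):
        feats = pd.DataFrame({"x": [0.0] * 10}, index=[f"s{i}" for i in range(10)])
        y = np.array([1.0] * 3 + [0.0] * 7)
        model = fit_logistic(feats, y)
        assert model.dropped_constant == ["x"]
        scores = model.predict(feats)
        np.testing.assert_allclose(scores, 0.3, atol=1e-6)

    def test_two_by_two_table_odds_ratio(self):
        """Saturated single-covariate fit: OR = (40*30)/(10*20) = 6.0."""
        x = [1.0] * 50 + [0.0] * 50
        y = np.array([1.0] * 40 + [0.0] * 10 + [1.0] * 20 + [0.0] * 30)
        feats = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(100)])
        model = fit_logistic(feats, y)
        assert model.converged
        assert math.exp(model.coef[1]) == pytest.approx(6.0, rel=1e-3)

    def test_perfect_separation_flagged_with_fallback(self):
        x = [1.0] * 10 + [0.0] * 10
        y = np.array([1.0] * 10 + [0.0] * 10)
        feats = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(20)])
        model = fit_logistic(feats, y)
        assert not model.converged
        scores = model.predict(feats)
        assert (scores[:10] > 0.5).all() and (scores[10:] < 0.5).all()

    def test_clinical_lr_complete_cases_counted(self):
        rng = np.random.default_rng(0)
        n = 60
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age_group": ["<4", "4-18", ">18"] * (n // 3),
                "sex": rng.choice(["male", "female"], n),
                "resection": rng.choice(["GTR", "STR"], n),
                "gain_1q": rng.integers(0, 2, n),
                "loss_6q": rng.integers(0, 2, n),
                "cdkn2a_loss": rng.integers(0, 2, n),
                "cdkn2b_loss": rng.integers(0, 2, n),
            }
        )
        df.loc[0, "sex"] = None
        feats = encode_clinical_features(df)
        outcomes = {
            f"s{i}": RELAPSE if rng.uniform() < 0.5 else NED for i in range(n)
        }
        model = clinical_lr(feats, outcomes)
        assert model.n_dropped_incomplete == 1
        assert model.n_train == n - 1

    def test_encode_reference_levels(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "age_group": ["<4", "4-18", ">18"],
                "sex": ["female", "male", "female"],
                "resection": ["GTR", "STR", "GTR"],
                "gain_1q": [0, 1, 0],
                "loss_6q": [0, 0, 1],
                "cdkn2a_loss": [0, 0, 0],
                "cdkn2b_loss": [1, 0, 0],
            }
        )
        feats = encode_clinical_features(df)
        assert list(feats.columns) == CLINICAL_COLUMNS
        assert feats.loc["a"].tolist() == [0, 0, 0, 0, 0, 0, 0, 1]
        assert feats.loc["b"].tolist() == [1, 0, 1, 1, 1, 0, 0, 0]
        assert feats.loc["c"].tolist() == [0, 1, 0, 0, 0, 1, 0, 0]


class TestIntegratedStack:
    def _setup(self, signal_setup, constant_svm=False):
        from ependysurv.predictors import NestedCVResult

        cohort, beta, outcomes, folds = signal_setup
        res = nested_cv_svm(beta, outcomes, folds, top_k=300, grid=reduced_grid(300))
        if constant_svm:
            res = NestedCVResult(
                predictions=[
                    ProbabilisticPrediction(p.sample_id, 0.5, p.label, p.outer_fold)
                    for p in res.predictions
                ],
                inner_scores={
                    f: {s: 0.5 for s in d} for f, d in res.inner_scores.items()
                },
                chosen_params=res.chosen_params,
                inner_losses=res.inner_losses,
            )
        feats = encode_clinical_features(cohort.annotations)
        return cohort, res, feats, outcomes, folds

    def test_constant_svm_scores_reduce_to_clinical(self, signal_setup):
        """With the SVM score constant at 0.5 it is dropped as zero-variance
        and the stack reproduces the clinical-only logistic model."""
        cohort, res, feats, outcomes, folds = self._setup(
            signal_setup, constant_svm=True
        )
        stacked = integrated_stack(res, feats, outcomes, folds)
        clinical = cv_clinical_lr(feats, outcomes, folds)
        s = {p.sample_id: p.score_relapse for p in stacked}
        c = {p.sample_id: p.score_relapse for p in clinical}
        assert s.keys() == c.keys()
        for sid in s:
            assert s[sid] == pytest.approx(c[sid], abs=1e-6)

    def test_informative_svm_dominates_noise_covariates(self, signal_setup):
        """Clinical covariates nearly uninformative here; the stacked model
        stays within a few points of the SVM alone."""
        from ependysurv.evaluate import accuracies, confusion

        cohort, res, feats, outcomes, folds = self._setup(signal_setup)
        stacked = integrated_stack(res, feats, outcomes, folds)
        b_svm = accuracies(confusion(res.predictions, outcomes))[1]
        b_stack = accuracies(confusion(stacked, outcomes))[1]
        assert b_stack >= b_svm - 0.05

    def test_trained_only_on_outer_training_scores(self, signal_setup):
        """The stack for fold f uses inner scores of fold f's training ids
        only; predictions exist exactly for scored complete-case test ids."""
        cohort, res, feats, outcomes, folds = self._setup(signal_setup)
        stacked = integrated_stack(res, feats, outcomes, folds)
        by_fold = {}
        for p in stacked:
            by_fold.setdefault(p.outer_fold, []).append(p.sample_id)
        for f, ids in by_fold.items():
            test = set(folds.outer_test_ids(f))
            assert set(ids) <= test
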