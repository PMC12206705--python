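"""SMOTE, cross-validation, tuning, SHAP importances and report metrics."""

import numpy as np
import pandas as pd
import pytest

from speechmarkers.model import (
    DEFAULT_XGB_PARAMS,
    ModelConfig,
    _make_xgb,
    _median_impute,
    classification_report_from_confusion,
    cv_with_infold_smote,
    mean_abs_shap,
    select_features,
    shap_contribution_table,
    smote_upsample,
    tune_hyperparameters,
)
from speechmarkers.optimize import ParamRange, bayes_optimize


def make_blobs(rng, counts, spread=0.3):
    """Well-separated class blobs in 2-d."""
    X, y = [], []
    for label, (count, center) in enumerate(counts):
        X.append(rng.normal(loc=center, scale=spread, size=(count, 2)))
        y.extend([label] * count)
    return np.vstack(X), np.array(y)


class TestSmote:
    def test_balances_all_classes_to_majority(self):
        rng = np.random.default_rng(0)
        X, y = make_blobs(rng, [(10, 0.0), (4, 5.0), (3, 10.0)])
        X2, y2 = smote_upsample(X, y, k_neighbors=2, seed=1)
        assert {c: int(n) for c, n in zip(*np.unique(y2, return_counts=True))} == {
            0: 10, 1: 10, 2: 10,
        }
        # originals are preserved verbatim at the front
        np.testing.assert_array_equal(X2[: len(X)], X)

    def test_synthetic_points_lie_on_minority_segments(self):
        rng = np.random.default_rng(1)
        X, y = make_blobs(rng, [(12, 0.0), (5, 8.0)])
        X2, y2 = smote_upsample(X, y, k_neighbors=3, seed=2)
        minority = X[y == 1]
        for point in X2[len(X):]:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    t = np.dot(point - minority[i], d) / np.dot(d, d)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(
                        minority[i] + t * d - point
                    ) < 1e-9:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_k_clipped_for_tiny_minority(self):
        rng = np.random.default_rng(2)
        X, y = make_blobs(rng, [(8, 0.0), (2, 5.0)])
        X2, y2 = smote_upsample(X, y, k_neighbors=5, seed=0)
        assert (y2 == 1).sum() == 8

    def test_singleton_class_is_an_error(self):
        rng = np.random.default_rng(3)
        X, y = make_blobs(rng, [(5, 0.0), (1, 5.0)])
        with pytest.raises(ValueError, match="k_folds|cohort"):
            smote_upsample(X, y, seed=0)

    def test_nan_input_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 1.0], [0.0, 1.0], [3.0, 2.0]])
        with pytest.raises(ValueError, match="impute"):
            smote_upsample(X, np.array([0, 0, 1, 1]), seed=0)


class TestCrossValidation:
    def test_fold_class_counts_for_default_cohort_sizes(self):
        rng = np.random.default_rng(0)
        y = np.array(["NAR"] * 15 + ["AR"] * 45 + ["FEP"] * 8)
        X = rng.normal(size=(68, 3))
        folds = cv_with_infold_smote(X, y, DEFAULT_XGB_PARAMS, ModelConfig(seed=0))
        assert len(folds) == 3
        for fold in folds:
            val_labels = y[fold.val_indices]
            assert (val_labels == "NAR").sum() == 5
            assert (val_labels == "AR").sum() == 15
            assert (val_labels == "FEP").sum() in (2, 3)

    def test_validation_partitions_contain_no_synthetic_samples(self):
        rng = np.random.default_rng(1)
        X, y = make_blobs(rng, [(15, 0.0), (45, 5.0), (8, 10.0)])
        folds = cv_with_infold_smote(X, y, DEFAULT_XGB_PARAMS, ModelConfig(seed=1))
        all_val = np.concatenate([f.val_indices for f in folds])
        # validation indices address original rows only, and cover them once
        assert sorted(all_val) == list(range(len(y)))
        for fold in folds:
            assert set(fold.val_indices).isdisjoint(fold.train_indices)
            assert fold.n_train_after_smote == 3 * max(
                np.bincount(np.searchsorted(np.unique(y), y[fold.train_indices]))
            )

    def test_separable_classes_reach_perfect_cv_accuracy(self):
        # class-coded feature: every validation value coincides with training
        # values, so any class-separating split scores the fold perfectly
        # (with continuous blobs a histogram split may hug a class's training
        # minimum and clip validation points just outside the training hull)
        rng = np.random.default_rng(2)
        y = np.array([0] * 15 + [1] * 45 + [2] * 8)
        X = np.column_stack([y.astype(float), rng.normal(size=len(y))])
        folds = cv_with_infold_smote(X, y, DEFAULT_XGB_PARAMS, ModelConfig(seed=2))
        assert np.mean([f.accuracy for f in folds]) == 1.0

    def test_infeasible_stratification_rejected(self):
        rng = np.random.default_rng(3)
        X, y = make_blobs(rng, [(10, 0.0), (2, 5.0)])
        with pytest.raises(ValueError, match="stratification"):
            cv_with_infold_smote(X, y, DEFAULT_XGB_PARAMS, ModelConfig(k_folds=3))


class TestBayesOptimization:
    SPACE = {
        "x": ParamRange(0.0, 1.0, "float"),
        "n": ParamRange(1, 10, "int"),
        "lr": ParamRange(1e-3, 1.0, "logfloat"),
    }

    def test_single_iteration_returns_that_point(self):
        calls = []
        best, value, history = bayes_optimize(
            lambda p: calls.append(p) or 0.5, self.SPACE, n_iter=1, seed=0
        )
        assert len(history) == 1 and best == calls[0] and value == 0.5

    def test_all_proposals_stay_inside_declared_ranges(self):
        seen = []
        bayes_optimize(lambda p: seen.append(p) or -(p["x"] - 0.7) ** 2,
                       self.SPACE, n_iter=50, seed=1)
        for p in seen:
            assert 0.0 <= p["x"] <= 1.0
            assert 1 <= p["n"] <= 10 and isinstance(p["n"], int)
            assert 1e-3 <= p["lr"] <= 1.0

    def test_finds_dominant_parameter_better_than_midpoint(self):
        def objective(p):
            return -((p["x"] - 0.9) ** 2)  # midpoint x=0.5 scores -0.16

        wins = 0
        for seed in range(10):
            best, value, _ = bayes_optimize(objective, self.SPACE, n_iter=15, seed=seed)
            if value > -0.16:
                wins += 1
        assert wins >= 8

    def test_reproducible_given_seed(self):
        rng_obj = lambda p: -((p["x"] - 0.3) ** 2) + p["n"] * 1e-3
        a = bayes_optimize(rng_obj, self.SPACE, n_iter=8, seed=5)
        b = bayes_optimize(rng_obj, self.SPACE, n_iter=8, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            bayes_optimize(lambda p: 0.0, {}, n_iter=3)

    def test_tuning_objective_reproducible(self):
        rng = np.random.default_rng(4)
        X, y = make_blobs(rng, [(12, 0.0), (12, 3.0), (12, 6.0)])
        cfg = ModelConfig(seed=9, bayes_opt_iterations=4)
        assert tune_hyperparameters(X, y, cfg) == tune_hyperparameters(X, y, cfg)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X, y = make_blobs(rng, [(20, 0.0), (20, 4.0), (20, 8.0)])
    # add one constant column the trees can never split on
    X = np.hstack([X, np.ones((len(X), 1))])
    clf = _make_xgb(DEFAULT_XGB_PARAMS, seed=0)
    clf.fit(X, y)
    return clf, X


class TestShap:

    def test_additivity_to_margin(self, fitted):
        import xgboost as xgb

        clf, X = fitted
        booster = clf.get_booster()
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        margins = booster.predict(xgb.DMatrix(X), output_margin=True)
        resid = np.abs(contribs.sum(axis=-1) - margins).max()
        assert resid < 1e-4  # float32 attributions

    def test_unsplit_feature_has_zero_importance(self, fitted):
        clf, X = fitted
        imp = mean_abs_shap(clf, X, ["a", "b", "const"])
        assert imp["const"] == 0.0
        assert (imp >= 0).all()

    def test_contribution_table_shape_and_additivity(self, fitted):
        import xgboost as xgb

        clf, X = fitted
        table = shap_contribution_table(clf, X, class_names=["n", "a", "f"],
                                        feature_names=["a", "b", "const"])
        assert len(table) == len(X) * 3 * 3
        margins = clf.get_booster().predict(xgb.DMatrix(X), output_margin=True)
        contribs = clf.get_booster().predict(xgb.DMatrix(X), pred_contribs=True)
        got = table.groupby(["sample", "class"], sort=False)["shap_value"].sum()
        # per (sample, class): sum of feature attributions + bias = margin
        for si in (0, 7, 31):
            for ci, cname in enumerate(["n", "a", "f"]):
                expected = margins[si, ci] - contribs[si, ci, -1]
                assert got.loc[(si, cname)] == pytest.approx(expected, abs=1e-4)


class TestFeatureSelection:
    def test_threshold_rule(self):
        imp = pd.Series({"a": 0.9, "b": 0.31, "c": 0.29})
        assert select_features(imp, ModelConfig(shap_threshold=0.3)) == ["a", "b"]

    def test_fallback_to_top_one_with_warning(self, caplog):
        imp = pd.Series({"a": 0.1, "b": 0.05})
        with pytest.warns(UserWarning, match="top-1"):
            assert select_features(imp, ModelConfig(shap_threshold=0.3)) == ["a"]

    def test_scan_mode_recovers_informative_features(self):
        """Top-m scan keeps a compact set containing the informative features."""
        rng = np.random.default_rng(0)
        n = 68
        informative = rng.normal(size=(n, 4))
        y = np.array(["NAR", "AR", "FEP"])[
            np.clip((informative[:, :2].sum(axis=1) > 0).astype(int)
                    + (informative[:, 2:4].sum(axis=1) > 1).astype(int), 0, 2)
        ]
        noise = rng.normal(size=(n, 21))
        X = np.hstack([informative, noise])
        names = [f"inf{i}" for i in range(4)] + [f"noise{i}" for i in range(21)]
        hits = 0
        for seed in range(6):
            cfg = ModelConfig(seed=seed, selection="scan", scan_top_n=10)
            clf = _make_xgb(DEFAULT_XGB_PARAMS, seed)
            enc = {c: i for i, c in enumerate(np.unique(y))}
            clf.fit(X, np.array([enc[v] for v in y]))
            imp = mean_abs_shap(clf, X, names)
            chosen = select_features(imp, cfg, cv_data=(X, y))
            if len(chosen) <= 8 and sum(f.startswith("inf") for f in chosen) >= 3:
                hits += 1
        assert hits >= 5

    def test_scan_without_cv_data_rejected(self):
        imp = pd.Series({"a": 0.9})
        with pytest.raises(ValueError, match="cv_data"):
            select_features(imp, ModelConfig(selection="scan"))


class TestClassificationReport:
    def test_published_report_arithmetic(self):
        """The unique integer confusion matrix consistent with the printed
        per-class report reproduces every printed aggregate."""
        cm = [[4, 1, 0], [3, 12, 0], [0, 0, 2]]
        rep = classification_report_from_confusion(cm, ["NAR", "AR", "FEP"], beta=2)
        assert round(rep.precision["NAR"], 2) == 0.57
        assert round(rep.precision["AR"], 2) == 0.92
        assert rep.precision["FEP"] == 1.0
        assert [round(rep.recall[c], 2) for c in ("NAR", "AR", "FEP")] == [
            0.80, 0.80, 1.00,
        ]
        assert round(rep.accuracy, 2) == 0.82
        assert round(rep.weighted["precision"], 2) == 0.85
        assert round(rep.macro["recall"], 2) == 0.87
        assert round(rep.macro["f1"], 2) == 0.84
        assert round(rep.specificity["AR"], 2) == 0.86
        assert round(rep.weighted["fbeta"], 2) == 0.82
        assert rep.support == {"NAR": 5, "AR": 15, "FEP": 2}

    def test_identity_matrix_is_perfect(self):
        rep = classification_report_from_confusion(np.eye(3) * 4, ["a", "b", "c"])
        for c in ("a", "b", "c"):
            assert rep.precision[c] == rep.recall[c] == rep.f1[c] == 1.0
        assert rep.accuracy == 1.0 and rep.macro["specificity"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_fuzz_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 9, size=(3, 3))
        cm[np.diag_indices(3)] += 1  # ensure nonzero rows
        rep = classification_report_from_confusion(cm, ["x", "y", "z"], beta=2)
        total = cm.sum()
        for i, c in enumerate(["x", "y", "z"]):
            tp = cm[i, i]
            fp = cm[:, i].sum() - tp
            fn = cm[i, :].sum() - tp
            tn = total - tp - fp - fn
            if tp + fp > 0:
                assert rep.precision[c] == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert rep.recall[c] == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert rep.specificity[c] == pytest.approx(tn / (tn + fp), abs=1e-12)
        assert rep.accuracy == pytest.approx(np.trace(cm) / total, abs=1e-12)
        # weighted averages recompute from per-class values and supports
        w = cm.sum(axis=1) / total
        recalc = sum(w[i] * rep.recall[c] for i, c in enumerate(["x", "y", "z"]))
        assert rep.weighted["recall"] == pytest.approx(recalc, abs=1e-12)

    def test_never_predicted_class_has_missing_precision(self):
        rep = classification_report_from_confusion(
            [[3, 1, 0], [1, 3, 0], [1, 1, 0]], ["a", "b", "c"]
        )
        assert np.isnan(rep.precision["c"])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            classification_report_from_confusion([[1, 2], [3, 4], [5, 6]], ["a", "b"])
        with pytest.raises(ValueError):
            classification_report_from_confusion(
                [[0, 0, 0], [1, 1, 1], [1, 1, 1]], ["a", "b", "c"]
            )


class TestImputation:
    def test_medians_come_from_training_block_only(self):
        train = np.array([[1.0, np.nan], [3.0, 2.0], [5.0, 4.0]])
        test = np.array([[np.nan, np.nan]])
        train_imp, test_imp, med = _median_impute(train, test)
        assert med[0] == 3.0 and med[1] == 3.0
        assert test_imp[0, 0] == 3.0 and test_imp[0, 1] == 3.0
        assert train_imp[0, 1] == 3.0
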