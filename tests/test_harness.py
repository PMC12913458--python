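import numpy as np
import pandas as pd
import pytest

from microdyn import ConfigError, schema
from microdyn.harness import (AttributionRanking, CLASSIFIER_IDS,
                              UnsupportedModelError, attribution_rank,
                              cross_validated_eval, cumulative_ablation,
                              evaluate_metrics, fit_full, topk_retrain,
                              _make_cv)


def _signal_table(rng, n=120, n_noise=10, sep=3.0, columns=None):
    """Binary-labeled table with one informative column plus noise."""
    y = np.repeat(["A", "B"], n // 2)
    signal = np.where(y == "B", sep, 0.0) + rng.normal(size=n)
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] = signal
    cols = columns or ["signal"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestEvaluateMetrics:
    def test_hand_worked_confusion(self):
        out = evaluate_metrics(tp=3, fp=2, tn=2, fn=1)
        assert out["sensitivity"] == pytest.approx(75.0)
        assert out["specificity"] == pytest.approx(50.0)
        assert out["accuracy"] == pytest.approx(62.5)
        assert out["f1"] == pytest.approx(200 / 3, abs=0.01)

    def test_perfect_predictions(self):
        out = evaluate_metrics(tp=5, fp=0, tn=5, fn=0)
        assert all(v == 100.0 for v in out.values())

    def test_always_positive_predictor(self):
        out = evaluate_metrics(tp=5, fp=5, tn=0, fn=0)
        assert out["sensitivity"] == 100.0
        assert out["specificity"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            evaluate_metrics(tp=-1, fp=0, tn=1, fn=0)

    def test_undefined_ratio_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = evaluate_metrics(tp=0, fp=0, tn=5, fn=0)
        assert np.isnan(out["sensitivity"])

    def test_matches_confusion_oracle_on_random_tables(self, rng):
        import warnings
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out = evaluate_metrics(int(tp), int(fp), int(tn), int(fn))
            assert out["accuracy"] == 100 * (tp + tn) / (tp + fp + tn + fn)
            if tp + fn:
                assert out["sensitivity"] == 100 * tp / (tp + fn)
            if tn + fp:
                assert out["specificity"] == 100 * tn / (tn + fp)


class TestCrossValidatedEval:
    def test_separable_cohort_scores_high(self, rng):
        table, y = _signal_table(rng, n=80, sep=4.0)
        res = cross_validated_eval(table, y, classifiers=("xgb",), folds=5,
                                   search_iters=0, seed=42)[0]
        assert res.mean("accuracy") >= 85.0
        assert res.unit == "subject"

    def test_permuted_labels_score_at_chance(self, rng):
        table, y = _signal_table(rng, n=100, sep=4.0)
        y_perm = rng.permutation(y)
        res = cross_validated_eval(table, y_perm, classifiers=("xgb",),
                                   folds=5, search_iters=0, seed=42)[0]
        assert 40.0 <= res.mean("accuracy") <= 60.0

    def test_same_seed_reproduces_everything(self, rng):
        table, y = _signal_table(rng, n=60)
        kwargs = dict(classifiers=("xgb",), folds=4, search_iters=3, seed=11)
        a = cross_validated_eval(table, y, **kwargs)[0]
        b = cross_validated_eval(table, y, **kwargs)[0]
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        assert a.roc_auc == b.roc_auc

    def test_unknown_classifier_rejected(self, rng):
        table, y = _signal_table(rng, n=40)
        with pytest.raises(ConfigError):
            cross_validated_eval(table, y, classifiers=("catboost",), folds=2)

    def test_non_finite_features_rejected(self, rng):
        table, y = _signal_table(rng, n=40)
        table.iloc[0, 0] = np.nan
        with pytest.raises(ConfigError):
            cross_validated_eval(table, y, classifiers=("xgb",), folds=2)

    def test_subject_unit_keeps_subject_rows_in_one_fold(self, rng):
        # 30 subjects x 4 epochs: no subject may straddle folds
        subjects = np.repeat([f"s{i}" for i in range(30)], 4)
        y = np.repeat(np.tile(["A", "B"], 15), 4)
        cv = _make_cv("subject", 5, 0)
        X = rng.normal(size=(120, 3))
        y_bin = (y == "B").astype(int)
        for tr, te in cv.split(X, y_bin, groups=subjects):
            assert set(subjects[tr]).isdisjoint(subjects[te])

    def test_full_roster_ids_are_available(self):
        assert set(CLASSIFIER_IDS) == {"logreg", "rf", "svm", "mlp", "xgb",
                                       "lgbm", "stack"}

    def test_roster_classifiers_run_on_tiny_problem(self, rng):
        table, y = _signal_table(rng, n=40, n_noise=3, sep=4.0)
        res = cross_validated_eval(table, y,
                                   classifiers=("logreg", "rf", "stack"),
                                   folds=2, search_iters=2, seed=0)
        assert [r.classifier for r in res] == ["logreg", "rf", "stack"]
        for r in res:
            assert 0.0 <= r.mean("accuracy") <= 100.0


class TestCumulativeAblation:
    def _schema_table(self, rng, n=60, spectral_effect=False):
        y = np.repeat(["A", "B"], n // 2)
        X = rng.normal(size=(n, 80))
        table = pd.DataFrame(X, columns=schema.FEATURE_NAMES)
        if spectral_effect:
            bump = np.where(y == "B", 2.5, 0.0)
            for col in schema.DOMAINS["spectral"][:4]:
                table[col] += bump + rng.normal(scale=0.3, size=n)
        return table, y

    def test_stage_column_counts(self, rng):
        table, y = self._schema_table(rng)
        out = cumulative_ablation(table, y, folds=3, search_iters=0, seed=1)
        assert out["n_features"].tolist() == [35, 55, 70, 80]

    def test_spectral_only_effect_lifts_stage_two(self, rng):
        table, y = self._schema_table(rng, spectral_effect=True)
        out = cumulative_ablation(table, y, folds=3, search_iters=0, seed=1)
        acc = out["accuracy_mean"].to_numpy()
        assert acc[1] > acc[0]

    def test_missing_domain_columns_rejected(self, rng):
        table, y = self._schema_table(rng)
        with pytest.raises(ConfigError):
            cumulative_ablation(table.drop(columns=["ngram_entropy"]), y,
                                folds=3, search_iters=0)


class TestAttribution:
    def test_constant_feature_gets_zero_attribution(self, rng):
        table, y = _signal_table(rng, n=80)
        table["flat"] = 1.0
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        assert rank.importances["flat"] == 0.0

    def test_local_accuracy_of_tree_shapley(self, rng):
        import xgboost
        table, y = _signal_table(rng, n=80)
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        margin = model.get_booster().predict(
            xgboost.DMatrix(table.to_numpy()), output_margin=True)
        recon = rank.values.sum(axis=1) + rank.base_value
        # float32 contributions: accumulate error slightly above 1e-6
        np.testing.assert_allclose(recon, margin, atol=1e-4)

    def test_single_informative_feature_ranks_first(self, rng):
        table, y = _signal_table(rng, n=120, sep=4.0)
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        assert rank.importances.index[0] == "signal"

    def test_lightgbm_attributions_supported(self, rng):
        table, y = _signal_table(rng, n=80, sep=4.0)
        model = fit_full(table, y, classifier="lgbm", seed=0)
        rank = attribution_rank(model, table)
        assert rank.method == "tree_shapley"
        assert rank.importances.index[0] == "signal"

    def test_non_tree_model_rejected_without_fallback(self, rng):
        from sklearn.linear_model import LogisticRegression
        table, y = _signal_table(rng, n=40)
        model = LogisticRegression().fit(table, (np.asarray(y) == "B"))
        with pytest.raises(UnsupportedModelError):
            attribution_rank(model, table)

    def test_permutation_fallback_is_flagged(self, rng):
        from sklearn.linear_model import LogisticRegression
        table, y = _signal_table(rng, n=60, sep=4.0)
        y_bin = (np.asarray(y) == "B").astype(int)
        model = LogisticRegression().fit(table, y_bin)
        with pytest.warns(RuntimeWarning):
            rank = attribution_rank(model, table,
                                    allow_permutation_fallback=True, y=y_bin)
        assert rank.method == "permutation"


class TestTopkRetrain:
    def test_identity_subset_reproduces_full_run(self, rng):
        table, y = _signal_table(rng, n=60, n_noise=5)
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        full = topk_retrain(table, y, rank, k=table.shape[1], folds=4, seed=3)
        from microdyn.harness import TOPK_GRID
        ref = cross_validated_eval(table, y, classifiers=("xgb",), folds=4,
                                   search_iters=1, seed=3, search="grid",
                                   param_grid=TOPK_GRID)[0]
        pd.testing.assert_frame_equal(full.fold_metrics, ref.fold_metrics)

    def test_single_informative_feature_is_enough(self, rng):
        table, y = _signal_table(rng, n=120, sep=4.0)
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        top1 = topk_retrain(table, y, rank, k=1, folds=5, seed=3)
        full = topk_retrain(table, y, rank, k=table.shape[1], folds=5, seed=3)
        assert top1.mean("accuracy") >= full.mean("accuracy") - 5.0

    def test_perfect_scorer_has_unit_auc(self, rng):
        # noise-free two-point signal: any split between the levels is exact
        y = np.repeat(["A", "B"], 30)
        table = pd.DataFrame(rng.normal(size=(60, 4)),
                             columns=["signal", "n0", "n1", "n2"])
        table["signal"] = np.where(y == "B", 50.0, 0.0)
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        res = topk_retrain(table, y, rank, k=1, folds=3, seed=3)
        assert res.roc_auc == pytest.approx(1.0)

    def test_k_beyond_feature_count_rejected(self, rng):
        table, y = _signal_table(rng, n=40)
        model = fit_full(table, y, classifier="xgb", seed=0)
        rank = attribution_rank(model, table)
        with pytest.raises(ConfigError):
            topk_retrain(table, y, rank, k=999)
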