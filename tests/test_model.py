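import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

import facekin as fk
from facekin.features import impute_with_medians
from facekin.model import stratified_split
from facekin.selection import apply_recipe, selection_recipe


def brute_force_auc(y, scores):
    """Concordant-pair count / (n1 * n0), ties counted half."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


@pytest.fixture
def separable_data(rng):
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(
        {
            "signal": y * 4.0 + rng.normal(0, 0.3, n),
            "noise": rng.normal(size=n),
        }
    )
    return X, y


class TestComputeMetrics:
    def test_balanced_accuracy_from_sensitivity_and_specificity(self):
        # 100 positives with 81 detected, 100 negatives with 89 rejected
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        scores = np.r_[
            np.where(np.arange(100) < 81, 0.9, 0.1),
            np.where(np.arange(100) < 89, 0.1, 0.9),
        ]
        m = fk.compute_metrics(y, scores)
        assert m["sensitivity"] == pytest.approx(0.81)
        assert m["specificity"] == pytest.approx(0.89)
        assert m["balanced_accuracy"] == pytest.approx(0.85)

    def test_perfect_predictions_give_ones(self):
        y = np.array([0, 0, 1, 1])
        m = fk.compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert all(m[k] == pytest.approx(1.0) for k in m)

    def test_auc_equals_concordant_pair_count(self, rng):
        y = np.array([0, 1, 0, 1, 1, 0])
        scores = np.array([0.3, 0.8, 0.5, 0.5, 0.9, 0.1])
        m = fk.compute_metrics(y, scores)
        assert m["roc_auc"] == pytest.approx(brute_force_auc(y, scores))

    def test_monotone_transform_leaves_auc_unchanged(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.uniform(size=40)
        a1 = fk.compute_metrics(y, s)["roc_auc"]
        a2 = fk.compute_metrics(y, 1 / (1 + np.exp(-7 * s)))["roc_auc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_truth_gives_nan_auc(self):
        m = fk.compute_metrics(np.ones(4, int), np.array([0.6, 0.7, 0.8, 0.9]))
        assert np.isnan(m["roc_auc"])
        assert m["sensitivity"] == 1.0


class TestFitPredict:
    def test_separable_data_training_accuracy_one(self, separable_data):
        X, y = separable_data
        model = fk.fit_adaboost_rf(X, y, fk.EnsembleConfig(n_estimators=20, seed=0))
        scores = fk.predict_scores(model, X)
        assert (np.asarray(scores > 0.5, int) == y).all()

    def test_scores_bounded_and_reproducible(self, separable_data):
        X, y = separable_data
        cfg = fk.EnsembleConfig(n_estimators=15, seed=3)
        s1 = fk.predict_scores(fk.fit_adaboost_rf(X, y, cfg), X)
        s2 = fk.predict_scores(fk.fit_adaboost_rf(X, y, cfg), X)
        assert np.all((s1 >= 0) & (s1 <= 1))
        assert np.array_equal(s1, s2)

    def test_prediction_on_training_rows_is_stable(self, separable_data):
        X, y = separable_data
        model = fk.fit_adaboost_rf(X, y, fk.EnsembleConfig(n_estimators=10, seed=1))
        assert np.array_equal(fk.predict_scores(model, X), fk.predict_scores(model, X))

    def test_weights_and_learners_exposed(self, separable_data):
        X, y = separable_data
        cfg = fk.EnsembleConfig(n_estimators=12, seed=0)
        model = fk.fit_adaboost_rf(X, y, cfg)
        assert 1 <= len(model.weak_learners) <= 12
        assert np.all(np.isfinite(model.weights))

    def test_single_class_and_degenerate_rows_rejected(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError):
            fk.fit_adaboost_rf(X, np.zeros_like(y))
        constant = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        with pytest.raises(fk.model.FitError if hasattr(fk, "model") else Exception):
            fk.fit_adaboost_rf(constant, np.r_[np.zeros(5, int), np.ones(5, int)])


class TestSplitsAndRoc:
    def test_stratified_split_arithmetic_58_70(self):
        groups = np.array(["ARMS"] * 58 + ["CONTROL"] * 70)
        train, test = stratified_split(groups, 0.7, np.random.default_rng(0))
        assert train.sum() == 89  # 40 + 49
        assert test.sum() == 39
        assert (groups[train] == "ARMS").sum() == 40
        assert (groups[test] == "ARMS").sum() == 18

    def test_mean_roc_identical_curves_zero_sd(self):
        fpr = np.array([0.0, 0.2, 1.0])
        tpr = np.array([0.0, 0.9, 1.0])
        out = fk.mean_roc_curve([(fpr, tpr)] * 5)
        assert np.allclose(out["sd_tpr"], 0.0)
        assert out["mean_tpr"].iloc[0] == 0.0 and out["mean_tpr"].iloc[-1] == 1.0

    def test_mean_curve_auc_consistent_with_per_split_aucs(self, rng):
        curves = []
        aucs = []
        for _ in range(10):
            y = rng.integers(0, 2, 50)
            y[:2] = [0, 1]
            s = y + rng.normal(0, 0.8, 50)
            from sklearn.metrics import roc_auc_score, roc_curve

            fpr, tpr, _ = roc_curve(y, s)
            curves.append((fpr, tpr))
            aucs.append(roc_auc_score(y, s))
        out = fk.mean_roc_curve(curves)
        mean_auc = np.trapezoid(out["mean_tpr"], out["fpr"])
        assert abs(mean_auc - np.mean(aucs)) < np.std(aucs) + 0.02


class TestPermutationImportance:
    def _model(self, rng):
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {
                "signal": y * 3.0 + rng.normal(0, 0.4, n),
                "constant": np.ones(n),
                "noise": rng.normal(size=n),
            }
        )
        model = fk.fit_adaboost_rf(X, y, fk.EnsembleConfig(n_estimators=15, seed=0))
        return model, X, y

    def test_unused_feature_has_zero_importance(self, rng):
        model, X, y = self._model(rng)
        imp = fk.permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert imp["constant"] == pytest.approx(0.0, abs=1e-12)

    def test_informative_feature_strictly_largest(self, rng):
        model, X, y = self._model(rng)
        imp = fk.permutation_importance(model, X, y, n_repeats=10, seed=0)
        assert imp["signal"] > imp["noise"]
        assert imp["signal"] > 0.2

    def test_deterministic_given_seed(self, rng):
        model, X, y = self._model(rng)
        i1 = fk.permutation_importance(model, X, y, n_repeats=5, seed=4)
        i2 = fk.permutation_importance(model, X, y, n_repeats=5, seed=4)
        pd.testing.assert_series_equal(i1, i2)

    def test_agrees_with_sklearn_permutation_importance(self, rng):
        from sklearn.inspection import permutation_importance as sk_pi
        from sklearn.metrics import make_scorer, f1_score

        model, X, y = self._model(rng)
        ours = fk.permutation_importance(model, X, y, n_repeats=30, seed=0)
        theirs = sk_pi(
            model.model,
            X.to_numpy(),
            y,
            scoring=make_scorer(f1_score),
            n_repeats=30,
            random_state=0,
        ).importances_mean
        assert np.allclose(ours.to_numpy(), theirs, atol=0.05)


SMALL_SEL = fk.SelectionConfig(stage1_top_m=8, final_top_k=5, booster_rounds=25)
SMALL_ENS = fk.EnsembleConfig(n_estimators=15)


class TestMonteCarloCV:
    def test_balanced_accuracy_identity_every_split(self, small_table):
        table, labels = small_table
        res = fk.monte_carlo_cv(
            table, labels, n_splits=4, selection_config=SMALL_SEL,
            ensemble_config=SMALL_ENS, seed=0,
        )
        ps = res.per_split
        assert np.allclose(
            ps["balanced_accuracy"], (ps["sensitivity"] + ps["specificity"]) / 2
        )

    def test_summary_ordering_and_determinism(self, small_table):
        table, labels = small_table
        kw = dict(
            n_splits=3, selection_config=SMALL_SEL, ensemble_config=SMALL_ENS, seed=9
        )
        r1 = fk.monte_carlo_cv(table, labels, **kw)
        r2 = fk.monte_carlo_cv(table, labels, **kw)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        pd.testing.assert_frame_equal(r1.per_split, r2.per_split)
        s = r1.summary
        assert (s["max"] + 1e-12 >= s["mean"]).all() and (s["mean"] >= s["min"] - 1e-12).all()

    def test_no_information_flows_from_test_rows(self, small_cohort, small_table):
        """Perturbing held-out rows never changes selection or the fit."""
        table, labels = small_table
        ids = table.participant_ids
        groups = labels.groups(ids)
        rng = np.random.default_rng(np.random.SeedSequence([0, 0, 0]))
        train, test = stratified_split(groups, 0.7, rng)
        train_ids = [i for i, m in zip(ids, train) if m]

        def run(raw):
            ear_q1, mar_q1 = raw.pooled_q1(train_ids)
            base = raw.table_with_reference(ear_q1, mar_q1).loc[ids]
            base_train, medians = impute_with_medians(base[train])
            cfg = dataclasses.replace(SMALL_SEL, seed=123)
            selected = fk.select_features(base_train, groups[train], cfg)
            X_train = apply_recipe(base_train, selection_recipe(selected))
            model = fk.fit_adaboost_rf(
                X_train, groups[train], dataclasses.replace(SMALL_ENS, seed=5)
            )
            return selected, fk.predict_scores(model, X_train)

        sel_before, scores_before = run(table.raw)

        mutated = dataclasses.replace(
            table.raw,
            static=table.raw.static.copy(),
            ear_series=dict(table.raw.ear_series),
        )
        test_ids = [i for i, m in zip(ids, test) if m]
        mutated.static.loc[test_ids] = mutated.static.loc[test_ids] * 100 + 7.0
        for tid in test_ids:
            mutated.ear_series[tid] = mutated.ear_series[tid] * 0.1
        sel_after, scores_after = run(mutated)

        assert sel_before == sel_after
        assert np.array_equal(scores_before, scores_after)

    def test_selected_features_resolvable_on_test_rows(self, small_table):
        table, labels = small_table
        res = fk.monte_carlo_cv(
            table, labels, n_splits=2, selection_config=SMALL_SEL,
            ensemble_config=SMALL_ENS, seed=2,
        )
        for selected in res.selected_features:
            assert len(selected) == SMALL_SEL.final_top_k
            recipe = selection_recipe(selected)
            rebuilt = apply_recipe(table.data, recipe)
            assert list(rebuilt.columns) == selected

    def test_too_small_class_rejected(self, small_table):
        table, labels = small_table
        groups = np.array(["ARMS"] + ["CONTROL"] * 14)
        with pytest.raises(ValueError):
            fk.monte_carlo_cv(table, groups, n_splits=2)
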