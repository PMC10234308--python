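"""Split plan, tuning, ensemble vote, metrics, and cross-species transfer."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from snoexpress import predictor
from snoexpress.feature_assembly import TOP4_FEATURES, apply_scaler


def _ids_labels(n, n_pos, prefix="g"):
    ids = [f"{prefix}{k:04d}" for k in range(n)]
    labels = pd.Series([1] * n_pos + [0] * (n - n_pos), index=ids)
    return ids, labels


class TestSplitPlan:
    def test_partition_and_stratification(self):
        ids, labels = _ids_labels(1000, 300)
        plan = predictor.make_split_plan(ids, labels, seed=1)
        seen = []
        for s in plan.iterations:
            assert len(s.test) == 100
            n_pos = sum(labels[i] for i in s.test)
            assert abs(n_pos - 30) <= 1
            for name, frac in (("tuning", 0.1), ("training", 0.8)):
                subset = getattr(s, name)
                assert abs(len(subset) - frac * 1000) <= 1
                ratio = sum(labels[i] for i in subset) / len(subset)
                assert abs(ratio - 0.3) <= 1 / len(subset) + 1e-9
            seen.extend(s.test)
        assert sorted(seen) == sorted(ids)

    def test_minimal_cohort_gives_singleton_test_sets(self):
        ids, labels = _ids_labels(20, 10)
        plan = predictor.make_split_plan(ids, labels, seed=0)
        for s in plan.iterations:
            assert len(s.test) == 2
            assert {labels[i] for i in s.test} == {0, 1}

    def test_class_smaller_than_iterations_rejected(self):
        ids, labels = _ids_labels(100, 5)
        with pytest.raises(ValueError, match="each class"):
            predictor.make_split_plan(ids, labels, seed=0)

    def test_inconsistent_fractions_rejected(self):
        ids, labels = _ids_labels(100, 30)
        with pytest.raises(ValueError, match="test fraction"):
            predictor.make_split_plan(ids, labels, n_iter=5, seed=0)

    def test_seed_determinism_and_set_algebra(self):
        ids, labels = _ids_labels(200, 60)
        a = predictor.make_split_plan(ids, labels, seed=7)
        b = predictor.make_split_plan(ids, labels, seed=7)
        assert a == b
        c = predictor.make_split_plan(ids, labels, seed=8)
        assert a != c
        # independent set-algebra verification
        universe = set(ids)
        tests = [set(s.test) for s in a.iterations]
        assert set().union(*tests) == universe
        for s1, s2 in itertools.combinations(tests, 2):
            assert not (s1 & s2)
        for s in a.iterations:
            assert set(s.tuning) | set(s.training) | set(s.test) == universe
            assert not (set(s.tuning) & set(s.training))


class TestTune:
    @pytest.fixture
    def toy(self, rng):
        X = pd.DataFrame({"x1": np.r_[rng.normal(-2, 0.3, 30), rng.normal(2, 0.3, 30)],
                          "x2": rng.normal(0, 1, 60)})
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        return X, y

    def test_single_point_grid_returned(self, toy):
        X, y = toy
        assert predictor.tune("logistic_regression", X, y, {"C": [0.5]}, seed=0) == {"C": 0.5}

    def test_better_point_wins(self, rng):
        # imbalanced clusters: a whole-training-set neighborhood votes with
        # the majority class, k=3 separates
        X = pd.DataFrame({"x1": np.r_[rng.normal(-2, 0.3, 40), rng.normal(2, 0.3, 20)],
                          "x2": rng.normal(0, 1, 60)})
        y = np.r_[np.zeros(40), np.ones(20)].astype(int)
        best = predictor.tune("knn", X, y, {"n_neighbors": [39, 3]}, seed=0)
        assert best == {"n_neighbors": 3}

    def test_tie_goes_to_first_declared_point(self, toy):
        X, y = toy
        # both regularization strengths separate the toy data perfectly
        best = predictor.tune("logistic_regression", X, y, {"C": [1e-10, 1.0]}, seed=0)
        assert best == {"C": 1e-10}

    def test_matches_manual_grid_evaluation(self, toy):
        X, y = toy
        grid = {"C": [0.01, 1.0], "kernel": ["linear", "rbf"]}
        best = predictor.tune("svm", X, y, grid, seed=3)
        from sklearn.model_selection import cross_val_score

        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=3)
        scores = {}
        for C in grid["C"]:
            for kernel in grid["kernel"]:
                est = predictor.build_estimator("svm", {"C": C, "kernel": kernel}, 3)
                scores[(C, kernel)] = cross_val_score(est, X, y, cv=cv).mean()
        expected = max(scores, key=lambda k: scores[k])
        assert scores[(best["C"], best["kernel"])] == scores[expected]

    def test_class_too_small_for_folds_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="3-fold"):
            predictor.tune("logistic_regression", X, y, {"C": [1.0]}, seed=0)


class TestTrainPredict:
    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        X = pd.DataFrame({"a": np.r_[rng.normal(-3, 0.1, 20), rng.normal(3, 0.1, 20)],
                          "b": rng.normal(size=40)})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        model = predictor.train("logistic_regression", {"C": 10.0}, X, y, seed=0)
        statuses, scores = predictor.predict_status(model, X)
        assert (statuses == y).all()
        assert ((scores > 0.5) == y.astype(bool)).all()

    def test_duplicated_rows_equal_double_weights(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = (rng.random(30) < 0.5).astype(int)
        dup = predictor.train(
            "logistic_regression", {"C": 1.0}, pd.concat([X, X]), np.r_[y, y], seed=0
        )
        weighted = predictor.build_estimator("logistic_regression", {"C": 1.0}, 0)
        weighted.fit(X, y, sample_weight=np.full(30, 2.0))
        np.testing.assert_allclose(dup.coef_, weighted.coef_, atol=1e-4)

    def test_same_seed_same_predictions(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = (X["a"] + rng.normal(0, 0.5, 60) > 0).astype(int)
        runs = [
            predictor.predict_status(
                predictor.train("random_forest", {"n_estimators": 30}, X, y, seed=9), X
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])


class TestEnsembleVote:
    def test_all_combinations_match_counting_oracle(self):
        for votes in itertools.product([0, 1], repeat=3):
            assert predictor.ensemble_vote(votes) == int(sum(votes) > 1.5)

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(ValueError):
            predictor.ensemble_vote([1, 0])


class TestMetrics:
    def _frame(self, truth, status, score):
        return pd.DataFrame(
            {"truth": truth, "ensemble_status": status, "ensemble_score": score}
        )

    def test_perfect_scores_give_unit_auc(self):
        df = self._frame([0, 0, 1, 1], [0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        m = predictor.confusion_and_metrics(df)
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0
        assert (m["TP"], m["TN"], m["FP"], m["FN"]) == (2, 2, 0, 0)

    def test_random_scores_near_half_auc(self, rng):
        truth = rng.integers(0, 2, 10000)
        score = rng.random(10000)
        m = predictor.confusion_and_metrics(self._frame(truth, (score > 0.5).astype(int), score))
        assert abs(m["auc"] - 0.5) < 0.02

    def test_auc_equals_mannwhitney_concordance(self, rng):
        truth = rng.integers(0, 2, 50)
        truth[:5], truth[-5:] = 1, 0  # both classes present
        score = rng.random(50)
        m = predictor.confusion_and_metrics(self._frame(truth, (score > 0.5).astype(int), score))
        pos, neg = score[truth == 1], score[truth == 0]
        pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
        assert m["auc"] == pytest.approx(np.mean(pairs))

    def test_single_class_truth_has_undefined_auc(self):
        m = predictor.confusion_and_metrics(self._frame([1, 1], [1, 0], [0.9, 0.2]))
        assert m["auc"] is None

    def test_identities_on_protocol_output(self, medium_protocol):
        m = predictor.confusion_and_metrics(medium_protocol.predictions)
        assert m["accuracy"] == pytest.approx((m["TP"] + m["TN"]) / m["n"])
        assert m["sensitivity"] == pytest.approx(m["TP"] / (m["TP"] + m["FN"]))
        assert m["specificity"] == pytest.approx(m["TN"] / (m["TN"] + m["FP"]))
        counts = medium_protocol.predictions["confusion"].value_counts()
        for key in ("TP", "TN", "FP", "FN"):
            assert m[key] == counts.get(key, 0)


class TestProtocol:
    def test_every_snorna_predicted_exactly_once(self, medium_protocol, medium_features):
        preds = medium_protocol.predictions
        assert sorted(preds.index) == sorted(medium_features.table.data.index)
        assert preds.index.is_unique

    def test_ensemble_overruled_only_by_two_against_one(self, medium_protocol):
        preds = medium_protocol.predictions
        for family in medium_protocol.ensemble_families:
            others = [f for f in medium_protocol.ensemble_families if f != family]
            disagree = preds["ensemble_status"] != preds[f"{family}_status"]
            two_against = (
                (preds[f"{others[0]}_status"] == preds[f"{others[1]}_status"])
                & (preds[f"{others[0]}_status"] != preds[f"{family}_status"])
            )
            assert (disagree == two_against).all()

    def test_truth_matches_labels(self, medium_protocol, medium_features):
        y = medium_features.table.y
        assert (medium_protocol.predictions["truth"] == y.loc[medium_protocol.predictions.index]).all()


class TestCrossSpecies:
    def test_in_sample_consistency_and_transfer(self, medium_features, smoke_cohort):
        table = medium_features.table
        model, stats, _ = predictor.fit_cross_species_model(table, seed=42)
        # consistency: scoring the human rows reproduces in-sample predictions
        human_top4 = table.X[TOP4_FEATURES]
        preds, proportion = predictor.cross_species_predict(model, stats, human_top4)
        direct, _ = predictor.predict_status(model, apply_scaler(stats, human_top4))
        np.testing.assert_array_equal(preds["status"].to_numpy(), direct)
        assert 0 <= proportion <= 1

    def test_column_mismatch_rejected(self, medium_features):
        table = medium_features.table
        model, stats, _ = predictor.fit_cross_species_model(table, seed=42)
        with pytest.raises(ValueError, match="columns"):
            predictor.cross_species_predict(
                model, stats, table.X[list(reversed(TOP4_FEATURES))]
            )

    def test_transfer_recovers_species_expressed_proportion(
        self, medium_features, smoke_features
    ):
        """A reduced model trained on one cohort estimates another cohort's
        expressed fraction (tolerance reflects the n=50 species size)."""
        model, stats, _ = predictor.fit_cross_species_model(
            medium_features.table, seed=42
        )
        species = smoke_features.table.X[TOP4_FEATURES]
        _, proportion = predictor.cross_species_predict(model, stats, species)
        truth = smoke_features.table.y.mean()
        assert abs(proportion - truth) <= 0.15

    def test_anti_ordered_proportions_give_negative_correlation(self):
        r, _ = predictor.expressed_proportion_count_correlation(
            [0.6, 0.4, 0.2], [100, 900, 2000]
        )
        assert r < 0
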