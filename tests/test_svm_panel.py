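"""Linear SVM, greedy forward selection and the nested-CV panel wrapper."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from metamark import (aggregate_panel, greedy_forward_select,
                      nested_cv_evaluate, train_linear_margin_classifier)


def _svm_objective(w, b, X, y, cost):
    margins = 1 - y * (X @ w + b)
    return 0.5 * np.dot(w, w) + cost * np.clip(margins, 0, None).sum()


class TestLinearMarginClassifier:
    def test_separable_1d_boundary_between_classes(self):
        X = np.array([[0.0], [0.5], [10.0], [9.5]])
        y = np.array([-1, -1, 1, 1])
        w, b = train_linear_margin_classifier(X, y)
        pred = np.sign(X @ w + b)
        assert np.array_equal(pred, y)
        boundary = -b / w[0]
        assert 0.5 < boundary < 9.5

    def test_duplicated_dataset_identical_weights(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        w1, b1 = train_linear_margin_classifier(X, y)
        w2, b2 = train_linear_margin_classifier(X, y)
        assert np.array_equal(w1, w2) and b1 == b2

    def test_near_optimal_against_grid_search(self, rng):
        """Objective value of the fitted classifier matches a brute-force
        grid search over (w, b) minimizing the same hinge + L2 objective."""
        for trial in range(3):
            local = np.random.default_rng(trial)
            X = local.normal(size=(8, 2))
            y = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
            X[y > 0] += 1.5
            w, b = train_linear_margin_classifier(X, y, cost=1.0)
            ours = _svm_objective(w, b, X, y, 1.0)
            grid = np.linspace(-3, 3, 41)
            best = min(_svm_objective(np.array([w1, w2]), bb, X, y, 1.0)
                       for w1 in grid for w2 in grid for bb in grid)
            assert ours <= best + 1e-3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_margin_classifier(np.zeros((4, 2)), np.ones(4))


class TestGreedyForwardSelect:
    def test_perfect_feature_chosen_first(self, rng):
        y = np.array([1] * 6 + [-1] * 6)
        X = rng.normal(size=(12, 5))
        X[:, 3] = y * 5.0
        path, acc_path, best_len = greedy_forward_select(X, y)
        assert path[0] == 3
        assert acc_path[0] == 1.0
        assert best_len == 1

    def test_path_capped_at_half_the_features(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array([1] * 6 + [-1] * 6)
        path, _, _ = greedy_forward_select(X, y, max_fraction=0.5)
        assert len(path) == 2

    def test_never_beats_exhaustive_subset_search(self, rng):
        """Greedy inner accuracy <= optimum over all subsets of size <= cap,
        evaluated with identical folds; ties make them equal."""
        equal_cases = 0
        for trial in range(5):
            local = np.random.default_rng(trial)
            X = local.normal(size=(12, 6))
            y = np.array([1] * 6 + [-1] * 6)
            X[:, 0] += y * 1.2
            path, acc_path, best_len = greedy_forward_select(
                X, y, inner_folds=3, seed=trial)
            greedy_best = max(acc_path)

            cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=trial)
            folds = list(cv.split(X, y))

            def subset_acc(cols):
                correct = total = 0
                for tr, te in folds:
                    mu = X[tr].mean(0)
                    sd = np.where(X[tr].std(0, ddof=1) < 1e-12, 1.0,
                                  X[tr].std(0, ddof=1))
                    clf = SVC(kernel="linear", C=1.0)
                    clf.fit(((X[tr] - mu) / sd)[:, cols], y[tr])
                    pred = clf.predict(((X[te] - mu) / sd)[:, cols])
                    correct += int((pred == y[te]).sum())
                    total += len(te)
                return correct / total

            exhaustive_best = max(
                subset_acc(list(cols))
                for size in (1, 2, 3)
                for cols in itertools.combinations(range(6), size))
            assert greedy_best <= exhaustive_best + 1e-12
            equal_cases += int(np.isclose(greedy_best, exhaustive_best))
        assert equal_cases >= 1


class TestNestedCvEvaluate:
    def test_separated_data_high_accuracy(self, rng):
        y = np.array(["T"] * 7 + ["C"] * 7)
        X = rng.normal(size=(14, 6))
        X[:, 2] += np.where(y == "T", 10.0, 0.0)
        rep = nested_cv_evaluate(X, y, "T", repeats=2, seed=0)
        assert rep.accuracy >= 95.0

    def test_same_seed_identical_report(self, rng):
        X = rng.normal(size=(14, 8))
        y = np.array(["T"] * 7 + ["C"] * 7)
        r1 = nested_cv_evaluate(X, y, "T", repeats=2, seed=3)
        r2 = nested_cv_evaluate(X, y, "T", repeats=2, seed=3)
        assert r1.metrics() == r2.metrics()
        assert r1.fold_records == r2.fold_records
        pd.testing.assert_frame_equal(r1.panel, r2.panel)

    def test_balanced_accuracy_is_mean_of_sens_spec(self, rng):
        X = rng.normal(size=(13, 5))
        y = np.array(["T"] * 6 + ["C"] * 7)
        X[:, 0] += np.where(y == "T", 1.0, 0.0)
        rep = nested_cv_evaluate(X, y, "T", repeats=2, seed=1)
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2, abs=1e-12)

    def test_class_smaller_than_fold_count_rejected(self, rng):
        X = rng.normal(size=(9, 4))
        y = np.array(["T"] * 2 + ["C"] * 7)
        with pytest.raises(ValueError, match="outer_folds"):
            nested_cv_evaluate(X, y, "T", outer_folds=3)

    def test_feature_permutation_leaves_metrics_unchanged(self, rng):
        y = np.array(["T"] * 7 + ["C"] * 7)
        X = rng.normal(size=(14, 6))
        X[:, 4] += np.where(y == "T", 8.0, 0.0)
        perm = np.array([4, 0, 5, 1, 3, 2])
        r1 = nested_cv_evaluate(X, y, "T", repeats=2, seed=2)
        r2 = nested_cv_evaluate(X[:, perm], y, "T", repeats=2, seed=2)
        assert r1.metrics() == r2.metrics()

    def test_held_out_sample_cannot_steer_selection(self, rng):
        """Perturbing one sample must not change the features selected in
        folds where that sample is held out."""
        y = np.array(["T"] * 6 + ["C"] * 6)
        X = rng.normal(size=(12, 5))
        X[:, 1] += np.where(y == "T", 2.0, 0.0)
        seed = 11
        X2 = X.copy()
        X2[0] += rng.normal(0, 5, size=5)

        r1 = nested_cv_evaluate(X, y, "T", repeats=1, seed=seed)
        r2 = nested_cv_evaluate(X2, y, "T", repeats=1, seed=seed)
        outer = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for k, (_, te) in enumerate(outer.split(X, y)):
            if 0 in te:
                assert r1.fold_records[k]["path"] == r2.fold_records[k]["path"]


class TestAggregatePanel:
    @staticmethod
    def _rec(panel, accs):
        return {"repeat": 0, "fold": 0, "panel": panel,
                "inner_accuracy_path": accs, "path": panel}

    def test_unanimous_folds_give_exactly_that_panel(self):
        recs = [self._rec(["a", "b", "c"], [0.8, 0.9, 1.0]) for _ in range(6)]
        panel = aggregate_panel(recs)
        assert set(panel.index[panel.in_panel]) == {"a", "b", "c"}

    def test_frequency_ranking_with_accuracy_tie_break(self):
        recs = []
        # A in every panel; B and C each in half; D once; modal size 2
        for i in range(10):
            if i < 5:
                recs.append(self._rec(["A", "B"], [0.7, 0.9]))
            elif i < 9:
                recs.append(self._rec(["A", "C"], [0.7, 0.8]))
            else:
                recs.append(self._rec(["C", "D"], [0.6, 0.5]))
        panel = aggregate_panel(recs)
        assert list(panel.index[:2]) == ["A", "B"]  # B beats C on accuracy
        assert panel.in_panel.sum() == 2

    def test_informative_features_dominate_pooled_frequencies(
            self, two_group_tables):
        info = [f"sig_{i}" for i in range(5)]
        records = []
        for seed in range(5):
            _, tlog, _ = two_group_tables(
                n_metabolites=20, seed=seed,
                effects={m: {"B": 2.5} for m in info})
            X = tlog.intensities.to_numpy()
            y = tlog.group_labels.to_numpy()
            rep = nested_cv_evaluate(X, y, "B", repeats=1, seed=seed,
                                     feature_names=tlog.metabolite_ids)
            records.extend(rep.fold_records)
        pooled = aggregate_panel(records)
        top10 = set(pooled.index[:10])
        assert len(top10 & set(info)) >= 3

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            aggregate_panel([])
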