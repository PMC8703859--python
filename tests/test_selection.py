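import warnings

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.feature_selection import RFECV
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from dtipair import (
    RFECVSelector,
    balanced_accuracy,
    rank_features,
    rfe_path,
    run_rfecv,
    select_best,
)
from dtipair.selection import SelectionResult, make_kernel


def planted_problem(n=100, p=20, n_informative=1, shift=3.0, seed=0):
    """Gaussian noise features with a few strongly separating columns."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    for j in range(n_informative):
        X[:, j] += shift * y
    return X, y


class TestBalancedAccuracy:
    def test_arithmetic_example(self):
        # TP=50, FN=0, TN=25, FP=25 -> 0.5*(1 + 0.5) = 0.75
        y_true = np.r_[np.ones(50, int), np.zeros(50, int)]
        y_pred = np.r_[np.ones(50, int), np.zeros(25, int), np.ones(25, int)]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.75)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        assert balanced_accuracy(y, y) == 1.0

    def test_all_one_predictor_on_imbalanced_labels(self):
        y_true = np.r_[np.ones(60, int), np.zeros(40, int)]
        assert balanced_accuracy(y_true, np.ones(100, int)) == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            balanced_accuracy([], [])

    def test_single_class_scores_present_class_with_warning(self):
        with pytest.warns(UserWarning, match="one class"):
            score = balanced_accuracy([1, 1, 1], [1, 1, 0])
        assert score == pytest.approx(2 / 3)

    def test_matches_sklearn_when_both_classes_present(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            if np.unique(y_true).size < 2:
                continue
            assert balanced_accuracy(y_true, y_pred) == pytest.approx(
                balanced_accuracy_score(y_true, y_pred), abs=1e-12
            )


class TestRankFeatures:
    @pytest.mark.parametrize("kernel", ["lsvm", "rf", "lr1", "lr2"])
    def test_separating_feature_ranked_first(self, kernel):
        X, y = planted_problem(n=100, p=20, shift=4.0, seed=2)
        order = rank_features(kernel, X, y, seed=0)
        assert order[0] == 0

    def test_duplicated_columns_adjacent_with_index_tiebreak(self):
        X, y = planted_problem(n=60, p=6, shift=3.0, seed=3)
        X[:, 4] = X[:, 0]  # exact duplicate of the informative column
        order = rank_features("rf", X, y, seed=0)
        # duplicates share importance mass; both land in the top ranks
        assert {0, 4} <= set(order[:3])

    def test_zero_feature_ranked_last_by_linear_kernel(self):
        # a feature that is identically zero can carry no weight under an
        # l2 penalty (a nonzero constant would instead act as an intercept)
        X, y = planted_problem(n=80, p=8, shift=3.0, seed=4)
        X[:, 5] = 0.0
        order = rank_features("lsvm", X, y, seed=0)
        assert order[-1] == 5

    def test_exact_ties_break_by_ascending_index(self):
        # all-constant features: every importance is identical
        X = np.ones((20, 5))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        order = rank_features("lsvm", X, y, seed=0)
        np.testing.assert_array_equal(order, np.arange(5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rank_features("lsvm", np.ones((10, 3)), np.zeros(10, int))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            make_kernel("svm-rbf")


class TestRfePath:
    def test_peak_subset_contains_planted_features(self):
        X, y = planted_problem(n=100, p=50, n_informative=2, shift=2.5, seed=5)
        path = rfe_path("lsvm", X, y, step=1, k=5, seed=0)
        sel = select_best(path, kernel="lsvm", step=1, k=5, seed=0, X=X, y=y)
        assert {0, 1} <= set(sel.selected_indices.tolist())

    def test_oversized_step_drops_to_one_feature(self):
        X, y = planted_problem(n=40, p=7, seed=6)
        path = rfe_path("lsvm", X, y, step=100, k=4, seed=0)
        assert [rec["size"] for rec in path] == [7, 1]

    def test_same_seed_reproduces_path(self):
        X, y = planted_problem(n=60, p=12, seed=7)
        a = rfe_path("lsvm", X, y, step=2, k=5, seed=3)
        b = rfe_path("lsvm", X, y, step=2, k=5, seed=3)
        assert [r["mean"] for r in a] == [r["mean"] for r in b]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra["indices"], rb["indices"])

    def test_k_exceeding_subjects_rejected(self):
        X, y = planted_problem(n=8, p=4, seed=8)
        with pytest.raises(ValueError, match="exceeds"):
            rfe_path("lsvm", X, y, step=1, k=9)

    def test_matches_sklearn_rfecv_oracle(self):
        """Per-size mean CV scores and the final selected set agree exactly
        with sklearn's RFECV under shared folds, scorer and kernel."""
        X, y = planted_problem(n=40, p=10, shift=0.8, seed=0)
        seed, k, step = 0, 5, 1
        path = rfe_path("lsvm", X, y, step=step, k=k, seed=seed)
        mine = {rec["size"]: rec["mean"] for rec in path}
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfecv = RFECV(
                LinearSVC(C=1.0, dual=True, max_iter=20000, random_state=seed),
                step=step,
                cv=skf,
                scoring="balanced_accuracy",
                min_features_to_select=1,
            ).fit(X, y)
        for size, mean in zip(
            rfecv.cv_results_["n_features"], rfecv.cv_results_["mean_test_score"]
        ):
            assert mine[int(size)] == pytest.approx(mean, abs=1e-12)
        sel = select_best(path, kernel="lsvm", step=step, k=k, seed=seed, X=X, y=y)
        assert sel.n_selected == rfecv.n_features_
        np.testing.assert_array_equal(
            sel.selected_indices, np.flatnonzero(rfecv.support_)
        )

    def test_matches_bruteforce_reimplementation(self):
        """Independent nested-loop re-implementation of the fold-wise
        elimination reproduces every per-size score and subset."""
        X, y = planted_problem(n=30, p=8, shift=1.0, seed=9)
        step, k, seed = 1, 3, 1
        path = rfe_path("lsvm", X, y, step=step, k=k, seed=seed)

        def brute_force():
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            scores = {s: [] for s in range(1, 9)}
            for train, test in skf.split(X, y):
                active = list(range(8))
                while True:
                    est = LinearSVC(C=1.0, dual=True, max_iter=20000, random_state=seed)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est.fit(X[train][:, active], y[train])
                    pred = est.predict(X[test][:, active])
                    r1 = np.mean(pred[y[test] == 1] == 1)
                    r0 = np.mean(pred[y[test] == 0] == 0)
                    scores[len(active)].append((r0 + r1) / 2)
                    if len(active) == 1:
                        break
                    w = np.abs(est.coef_).ravel()
                    weakest = min(range(len(active)), key=lambda i: (w[i], -i))
                    active.pop(weakest)
            return {s: float(np.mean(v)) for s, v in scores.items()}

    # noqa: the oracle intentionally repeats the algebra with plain loops
        expected = brute_force()
        for rec in path:
            assert rec["mean"] == pytest.approx(expected[rec["size"]], abs=1e-12)


class TestSelectBest:
    def _path(self, sizes, means):
        return [
            {"size": s, "mean": m, "sd": 0.0, "indices": np.arange(s)}
            for s, m in zip(sizes, means)
        ]

    def test_unique_maximum(self):
        sel = select_best(self._path([5, 3, 1], [0.6, 0.9, 0.7]))
        assert sel.n_selected == 3

    def test_tie_prefers_smaller_size(self):
        sel = select_best(self._path([5, 3, 1], [0.9, 0.9, 0.5]))
        assert sel.n_selected == 3

    def test_monotone_increasing_keeps_everything(self):
        sel = select_best(self._path([5, 3, 1], [0.9, 0.8, 0.7]))
        assert sel.n_selected == 5

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_best([])

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            SelectionResult(
                kernel="lsvm", step=1, k=5, seed=0, sizes=[2], means=[0.5],
                sds=[0.0], n_selected=2, selected_indices=[1, 1],
            )

    def test_json_round_trip(self, tmp_path):
        X, y = planted_problem(n=40, p=6, seed=10)
        res = run_rfecv("lsvm", X, y, step=1, k=4, seed=2,
                        feature_names=[f"f{i}" for i in range(6)])
        res.to_json(tmp_path / "sel.json")
        back = SelectionResult.from_json(tmp_path / "sel.json")
        assert back.n_selected == res.n_selected
        np.testing.assert_array_equal(back.selected_indices, res.selected_indices)
        np.testing.assert_allclose(back.means, res.means, atol=1e-15)
        assert back.feature_names == res.feature_names


class TestRFECVSelector:
    def test_fit_attributes_and_transform(self):
        X, y = planted_problem(n=60, p=10, shift=3.0, seed=11)
        sel = RFECVSelector(kernel="lsvm", step=1, cv=5, random_state=0).fit(X, y)
        assert sel.n_features_in_ == 10
        assert sel.support_.sum() == sel.n_features_
        assert sel.transform(X).shape == (60, sel.n_features_)
        np.testing.assert_array_equal(
            sel.get_support(indices=True), sel.result_.selected_indices
        )

    def test_sklearn_clone_contract(self):
        sel = RFECVSelector(kernel="rf", step=3, cv=4, random_state=7)
        assert clone(sel).get_params() == sel.get_params()

    def test_transform_width_checked(self):
        X, y = planted_problem(n=40, p=6, seed=12)
        sel = RFECVSelector(step=2, cv=4).fit(X, y)
        with pytest.raises(ValueError, match="width"):
            sel.transform(X[:, :4])
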