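"""Boosting algebra: folds, weight updates, CV prediction and error."""

import numpy as np
import pytest

from lboost.annealing import AnnealSchedule
from lboost.boosting import (
    BoostedForest,
    FoldPartition,
    WeightedTree,
    cv_misclassification,
    cv_predict,
    fit_lboost,
    make_folds,
    tree_cv_misclassification,
)
from lboost.logic import evaluate_tree, parse_tree, prime_implicants


class TestFolds:
    def test_exact_division(self, rng):
        part = make_folds(10, 5, rng)
        assert sorted(part.sizes()) == [2, 2, 2, 2, 2]

    def test_balance_rule_uneven(self, rng):
        part = make_folds(11, 5, rng)
        assert sorted(part.sizes()) == [2, 2, 2, 2, 3]

    def test_partition_property(self, rng):
        part = make_folds(23, 4, rng)
        all_test = np.concatenate([part.test_indices(k) for k in range(4)])
        assert sorted(all_test) == list(range(23))
        for k in range(4):
            assert not np.intersect1d(part.test_indices(k), part.train_indices(k)).size

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            make_folds(3, 5, rng)


def _manual_forest():
    """Two hand-built one-fold... two-fold forests for vote arithmetic tests."""
    trees = [
        WeightedTree(parse_tree("X1"), alpha=0.6, fold_id=0, weighted_error=0.2,
                     pis=tuple(prime_implicants(parse_tree("X1")))),
        WeightedTree(parse_tree("X2"), alpha=0.2, fold_id=0, weighted_error=0.4,
                     pis=tuple(prime_implicants(parse_tree("X2")))),
        WeightedTree(parse_tree("X1"), alpha=0.5, fold_id=1, weighted_error=0.3,
                     pis=tuple(prime_implicants(parse_tree("X1")))),
    ]
    partition = FoldPartition(K=2, assignment=np.array([0, 0, 1, 1]))
    return BoostedForest(
        trees=trees, partition=partition, A=2, max_size_cap=8,
        schedule=AnnealSchedule(n_iter=10),
    )


class TestCvPredict:
    def test_unanimous_vote(self):
        forest = _manual_forest()
        X = np.array([[1, 1]])
        assert cv_predict(forest, 0, X) == [1]

    def test_weighted_vote_dominates(self):
        """alphas (0.6, 0.2), predictions (1, 0): vote 0.4 > 0 so class 1."""
        forest = _manual_forest()
        X = np.array([[1, 0]])
        assert cv_predict(forest, 0, X) == [1]

    def test_zero_vote_breaks_to_zero(self):
        trees = [
            WeightedTree(parse_tree("X1"), 0.3, 0, 0.3,
                         tuple(prime_implicants(parse_tree("X1")))),
            WeightedTree(parse_tree("!X1"), 0.3, 0, 0.3,
                         tuple(prime_implicants(parse_tree("!X1")))),
        ]
        forest = BoostedForest(
            trees=trees, partition=FoldPartition(K=1, assignment=np.zeros(2, int)),
            A=2, max_size_cap=8, schedule=AnnealSchedule(n_iter=10),
        )
        assert cv_predict(forest, 0, np.array([[1], [0]])).tolist() == [0, 0]

    def test_single_tree_reduces_to_its_prediction(self, small_dd_data, fast_schedule):
        data, _ = small_dd_data
        forest = fit_lboost(data.X, data.y, K=2, A=1, schedule=fast_schedule, rng=3)
        for k in range(2):
            test = forest.partition.test_indices(k)
            entry = forest.fold_trees(k)[0]
            assert (
                cv_predict(forest, k, data.X[test])
                == evaluate_tree(entry.tree, data.X[test])
            ).all()


class TestFitLboost:
    def test_total_tree_count(self, small_dd_data, fast_schedule):
        data, _ = small_dd_data
        forest = fit_lboost(data.X, data.y, K=5, A=4, schedule=fast_schedule, rng=0)
        assert forest.n_trees == 20
        for k in range(5):
            assert len(forest.fold_trees(k)) == 4

    def test_alpha_err_relationship(self, small_dd_data, fast_schedule):
        data, _ = small_dd_data
        forest = fit_lboost(data.X, data.y, K=3, A=5, schedule=fast_schedule, rng=1)
        for t in forest.trees:
            assert t.alpha >= 0
            if t.weighted_error < 0.5:
                n_tr = len(forest.partition.train_indices(t.fold_id))
                eps = 1 / (2 * n_tr)
                err_c = min(max(t.weighted_error, eps), 0.5 - eps)
                assert t.alpha == pytest.approx(0.5 * np.log((1 - err_c) / err_c))

    def test_seeded_reproducibility(self, small_dd_data, fast_schedule):
        data, _ = small_dd_data
        f1 = fit_lboost(data.X, data.y, K=3, A=3, schedule=fast_schedule, rng=42)
        f2 = fit_lboost(data.X, data.y, K=3, A=3, schedule=fast_schedule, rng=42)
        assert [str(t.tree) for t in f1.trees] == [str(t.tree) for t in f2.trees]
        assert [t.alpha for t in f1.trees] == [t.alpha for t in f2.trees]
        assert (f1.partition.assignment == f2.partition.assignment).all()

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            fit_lboost(np.array([[2, 0], [1, 1]]), np.array([0, 1]))

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            fit_lboost(np.array([[1, 0], [0, 1]]), np.array([1, 1]))


class TestWeightUpdateIdentities:
    """Algebraic identities of the exponential reweighting scheme."""

    @staticmethod
    def _replay_weights(forest, X, y, fold_id):
        """Recompute the weight sequence for one fold from the stored trees."""
        train = forest.partition.train_indices(fold_id)
        X_tr, y_tr = X[train], y[train]
        n_tr = len(train)
        eps = 1 / (2 * n_tr)
        w = np.full(n_tr, 1 / n_tr)
        history = []
        for entry in forest.fold_trees(fold_id):
            mis = evaluate_tree(entry.tree, X_tr) != y_tr
            err = float(w[mis].sum())
            assert err == pytest.approx(entry.weighted_error)
            err_c = min(max(err, eps), 0.5 - eps)
            alpha = 0.5 * np.log((1 - err_c) / err_c)
            w = w * np.exp(alpha * np.where(mis, 1.0, -1.0))
            w /= w.sum()
            history.append((w.copy(), mis, err))
        return history

    def test_weights_normalized_and_post_update_error_half(
        self, small_dd_data, fast_schedule
    ):
        data, _ = small_dd_data
        forest = fit_lboost(data.X, data.y, K=3, A=6, schedule=fast_schedule, rng=9)
        n_tr = len(forest.partition.train_indices(0))
        eps = 1 / (2 * n_tr)
        for k in range(3):
            for w, mis, err in self._replay_weights(forest, data.X, data.y, k):
                assert w.sum() == pytest.approx(1.0, abs=1e-10)
                if eps <= err <= 0.5 - eps:  # unclamped: identity is exact
                    assert w[mis].sum() == pytest.approx(0.5, abs=1e-10)

    def test_worked_four_observation_example(self):
        """n = 4, uniform weights, one error: err 1/4, alpha ln(3)/2, weights (1/2, 1/6)."""
        w = np.full(4, 0.25)
        mis = np.array([True, False, False, False])
        err = float(w[mis].sum())
        assert err == pytest.approx(0.25)
        alpha = 0.5 * np.log((1 - err) / err)
        assert alpha == pytest.approx(0.5 * np.log(3))
        w = w * np.exp(alpha * np.where(mis, 1.0, -1.0))
        w /= w.sum()
        assert w[0] == pytest.approx(0.5)
        assert w[1:] == pytest.approx(np.full(3, 1 / 6))


class TestCvError:
    def test_perfect_forest_scores_zero(self):
        X = np.array([[1], [1], [0], [0]])
        y = np.array([1, 1, 0, 0])
        trees = [
            WeightedTree(parse_tree("X1"), 1.0, k, 0.0,
                         tuple(prime_implicants(parse_tree("X1"))))
            for k in range(2)
        ]
        forest = BoostedForest(
            trees=trees, partition=FoldPartition(K=2, assignment=np.array([0, 1, 0, 1])),
            A=1, max_size_cap=8, schedule=AnnealSchedule(n_iter=10),
        )
        assert cv_misclassification(forest, X, y) == 0.0

    def test_null_data_error_near_half(self, fast_schedule):
        """With y shuffled independently of X, CV error sits near 0.5."""
        rng = np.random.default_rng(17)
        X = rng.integers(0, 2, size=(400, 10))
        y = rng.permutation(np.repeat([0, 1], 200))
        forest = fit_lboost(X, y, K=5, A=5, schedule=fast_schedule, rng=rng)
        assert 0.4 <= cv_misclassification(forest, X, y) <= 0.6

    def test_complement_symmetry(self):
        X = np.array([[1], [1], [0], [0]])
        y = np.array([1, 1, 0, 0])
        mk = lambda expr: [
            WeightedTree(parse_tree(expr), 1.0, k, 0.0,
                         tuple(prime_implicants(parse_tree(expr))))
            for k in range(2)
        ]
        part = FoldPartition(K=2, assignment=np.array([0, 1, 0, 1]))
        sched = AnnealSchedule(n_iter=10)
        good = BoostedForest(trees=mk("X1"), partition=part, A=1,
                             max_size_cap=8, schedule=sched)
        bad = BoostedForest(trees=mk("!X1"), partition=part, A=1,
                            max_size_cap=8, schedule=sched)
        assert cv_misclassification(good, X, y) + cv_misclassification(
            bad, X, y
        ) == pytest.approx(1.0)


class TestTreeCvMisclassification:
    def test_count_ratio(self):
        """A tree predicting all 0 on a test set with 3 cases of 20 scores 0.15."""
        X = np.zeros((40, 2), dtype=int)
        y = np.zeros(40, dtype=int)
        assignment = np.repeat([0, 1], 20)
        y[20:23] = 1  # fold 1's test set has 3 cases of 20
        tree = parse_tree("X1")  # predicts 0 everywhere on X = 0
        entry = WeightedTree(tree, 1.0, 1, 0.0, tuple(prime_implicants(tree)))
        forest = BoostedForest(
            trees=[entry], partition=FoldPartition(K=2, assignment=assignment),
            A=1, max_size_cap=8, schedule=AnnealSchedule(n_iter=10),
        )
        assert tree_cv_misclassification(entry, forest, X, y) == pytest.approx(0.15)

    def test_equals_uniformly_weighted_misclassification(
        self, small_dd_data, fast_schedule
    ):
        from lboost.annealing import weighted_misclassification

        data, _ = small_dd_data
        forest = fit_lboost(data.X, data.y, K=4, A=2, schedule=fast_schedule, rng=8)
        for entry in forest.trees:
            test = forest.partition.test_indices(entry.fold_id)
            n_k = len(test)
            direct = tree_cv_misclassification(entry, forest, data.X, data.y)
            via_weights = weighted_misclassification(
                entry.tree, data.X[test], data.y[test], np.full(n_k, 1 / n_k)
            )
            assert direct == pytest.approx(via_weights)
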