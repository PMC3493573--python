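"""Permutation PI importance: matrices, V.LB, ranking, recovery, p-values."""

import numpy as np
import pytest

from lboost.annealing import AnnealSchedule
from lboost.boosting import BoostedForest, FoldPartition, WeightedTree, fit_lboost
from lboost.importance import (
    empirical_pvalue,
    pi_matrix,
    recovered,
    top_k_pis,
    v_lb,
)
from lboost.logic import parse_implicant, parse_tree, prime_implicants
import pandas as pd


def _entry(expr, fold_id=0, alpha=1.0):
    tree = parse_tree(expr)
    return WeightedTree(tree, alpha, fold_id, 0.0,
                        tuple(sorted(prime_implicants(tree), key=lambda pi: pi.key)))


def _forest(entries, assignment):
    K = int(np.max(assignment)) + 1
    return BoostedForest(
        trees=entries, partition=FoldPartition(K=K, assignment=np.asarray(assignment)),
        A=len(entries) // K, max_size_cap=8, schedule=AnnealSchedule(n_iter=10),
    )


class TestPiMatrix:
    def test_single_pi_column(self):
        entry = _entry("(X1 & X2)")
        P = pi_matrix(entry, np.array([[1, 1], [1, 0]]))
        assert P.tolist() == [[1], [0]]

    def test_or_of_columns_reproduces_tree(self, rng):
        entry = _entry("((X1 & !X2) | (X3 | X4))")
        X = rng.integers(0, 2, size=(30, 4))
        P = pi_matrix(entry, X)
        from lboost.logic import evaluate_tree

        assert (P.any(axis=1) == evaluate_tree(entry.tree, X).astype(bool)).all()

    def test_column_count_matches_pis(self):
        entry = _entry("((X1 & X2) | (X3 & X4))")
        assert pi_matrix(entry, np.zeros((5, 4), dtype=int)).shape == (5, 2)

    def test_degenerate_tree_flagged(self):
        entry = _entry("(X1 & !X1)")
        with pytest.warns(UserWarning, match="no prime implicants"):
            P = pi_matrix(entry, np.zeros((4, 1), dtype=int))
        assert P.shape == (4, 0)


class TestVlb:
    def test_constant_column_contributes_zero(self):
        """Permutation is the identity on a constant PI column."""
        X = np.ones((8, 1), dtype=int)
        y = np.array([1, 1, 1, 0, 1, 1, 1, 0])
        forest = _forest([_entry("X1", 0)], np.zeros(8, int))
        table = v_lb(forest, X, y, rng=0)
        assert table.loc[table.pi == "X1", "importance"].iloc[0] == 0.0

    def test_informative_pi_scores_positive(self):
        """A PI perfectly predicting a balanced test set loses accuracy when permuted."""
        rng = np.random.default_rng(1)
        X = np.repeat([1, 0], 10)[:, None].astype(int)
        y = X[:, 0].copy()
        forest = _forest([_entry("X1", 0)], np.zeros(20, int))
        table = v_lb(forest, X, y, rng=rng)
        assert table.loc[table.pi == "X1", "importance"].iloc[0] > 0

    def test_frequency_weighted_aggregation_across_trees(self, monkeypatch):
        """Contributions 0.10 and 0.20 in a 2-tree forest give V.LB 0.15.

        Like the bagging importance, V.LB normalizes the summed per-tree
        contributions by the total forest size, so presence in many trees
        raises a PI's rank.
        """
        from lboost import importance as imp

        from itertools import cycle

        contributions = cycle([[0.10], [0.20]])
        monkeypatch.setattr(
            imp, "_tree_contributions",
            lambda entry, P, y_test, mc_t, reps, rng: next(contributions),
        )
        X = np.ones((4, 2), dtype=int)
        y = np.array([0, 1, 0, 1])
        forest = _forest(
            [_entry("(X1 & X2)", 0), _entry("(X1 & X2)", 0)], np.zeros(4, int)
        )
        table = imp.v_lb(forest, X, y, rng=0)
        row = table.loc[table.pi == "X1&X2"]
        assert row["importance"].iloc[0] == pytest.approx(0.15)
        assert row["n_trees"].iloc[0] == 2

        # in a 4-tree forest with the PI in only 2 trees, the sum dilutes
        forest4 = _forest(
            [_entry("(X1 & X2)", 0), _entry("(X1 & X2)", 0),
             _entry("!X1", 0), _entry("!X2", 0)],
            np.zeros(4, int),
        )
        table4 = imp.v_lb(forest4, X, y, rng=0)
        row4 = table4.loc[table4.pi == "X1&X2"]
        assert row4["importance"].iloc[0] == pytest.approx(0.075)

    def test_unreferenced_pi_absent_not_zero(self):
        X = np.ones((4, 3), dtype=int)
        y = np.array([0, 1, 0, 1])
        forest = _forest([_entry("X1", 0)], np.zeros(4, int))
        table = v_lb(forest, X, y, rng=0)
        assert "X3" not in set(table.pi)

    def test_identity_permutation_zero_for_every_pi(self, small_dd_data, fast_schedule):
        """With the permutation forced to identity, every contribution is zero."""
        import lboost.importance as imp

        data, _ = small_dd_data
        forest = fit_lboost(data.X, data.y, K=3, A=3, schedule=fast_schedule, rng=2)

        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        stub = IdentityRng()
        for entry in forest.trees:
            if not entry.pis:
                continue
            test = forest.partition.test_indices(entry.fold_id)
            P = imp.pi_matrix(entry, data.X[test])
            mc_t = float((P.any(axis=1).astype(np.uint8) != data.y[test]).mean())
            contribs = imp._tree_contributions(
                entry, P, data.y[test], mc_t, 1, stub
            )
            assert contribs == pytest.approx([0.0] * len(contribs))


class TestTopK:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["pi", "importance", "n_trees"])

    def test_orders_by_absolute_value(self):
        table = self._table(
            [("X1", 0.1, 1), ("X2", -0.3, 1), ("X3", 0.2, 1)]
        )
        assert top_k_pis(table, k=2) == ["X2", "X3"]

    def test_ties_break_lexicographically(self):
        table = self._table([("X9", 0.2, 1), ("X2", 0.2, 1), ("X5", 0.2, 1)])
        assert top_k_pis(table, k=3) == ["X2", "X5", "X9"]

    def test_fewer_than_k_returns_all(self):
        table = self._table([("X1", 0.1, 1)])
        assert top_k_pis(table, k=20) == ["X1"]

    def test_union_across_tables(self):
        t1 = self._table([("X1", 0.4, 1), ("X2", 0.1, 1)])
        t2 = self._table([("X2", -0.5, 1), ("X3", 0.2, 1)])
        assert top_k_pis([t1, t2], k=2) == ["X2", "X1"]


class TestRecovered:
    def test_membership(self):
        assert recovered("X1&X2", ["X1&X2", "X5"])
        assert not recovered("X1&X3", ["X1&X2", "X5"])

    def test_ignores_literal_order_via_canonical_form(self):
        pi = parse_implicant("X2&X1")
        assert recovered(pi, ["X1&X2"])


class TestEmpiricalPvalue:
    def test_maximal_observed_gives_lower_bound(self):
        """A perfectly predictive PI achieves the smallest possible p-value."""
        X = np.repeat([1, 0], 20)[:, None].astype(int)
        y = X[:, 0].copy()
        forest = _forest([_entry("X1", 0)], np.zeros(40, int))
        p = empirical_pvalue(forest, X, y, "X1", n_perm=19, rng=3)
        assert p == pytest.approx(1 / 20)

    def test_constant_column_p_one(self):
        X = np.ones((10, 1), dtype=int)
        y = np.array([1] * 5 + [0] * 5)
        forest = _forest([_entry("X1", 0)], np.zeros(10, int))
        assert empirical_pvalue(forest, X, y, "X1", n_perm=19, rng=0) == 1.0

    def test_unknown_pi_rejected(self):
        X = np.ones((4, 1), dtype=int)
        y = np.array([0, 1, 0, 1])
        forest = _forest([_entry("X1", 0)], np.zeros(4, int))
        with pytest.raises(ValueError):
            empirical_pvalue(forest, X, y, "X9", n_perm=9, rng=0)

    def test_bad_n_perm_rejected(self):
        X = np.ones((4, 1), dtype=int)
        y = np.array([0, 1, 0, 1])
        forest = _forest([_entry("X1", 0)], np.zeros(4, int))
        with pytest.raises(ValueError):
            empirical_pvalue(forest, X, y, "X1", n_perm=0, rng=0)
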