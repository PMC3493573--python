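"""The LBoost algorithm: K-fold cross-validated boosting of logic trees.

For each cross-validation fold k the model boosts A logic trees on the
training portion: observation weights start uniform, each tree is fit by
simulated annealing on the current weights with a randomly drawn size cap,
its weighted error e determines the tree weight

    alpha = 1/2 * ln((1 - e) / e)       (e clamped away from 0 and 1/2),

and weights are multiplied by exp(+alpha) on misclassified and exp(-alpha)
on correctly classified observations, then renormalized — after which the
just-fitted tree's weighted error is exactly 1/2.  The forest holds all
K*A trees with their fold provenance; each fold's held-out subset serves
as that fold's test data for cross-validated prediction, misclassification
and the permutation importance measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annealing import AnnealSchedule, anneal_fit
from .logic import LogicTree, PrimeImplicant, evaluate_tree, prime_implicants

__all__ = [
    "FoldPartition",
    "WeightedTree",
    "BoostedForest",
    "make_folds",
    "fit_lboost",
    "cv_predict",
    "cv_misclassification",
    "tree_cv_misclassification",
]


@dataclass(frozen=True)
class FoldPartition:
    """A random balanced partition of n observations into K folds."""

    K: int
    assignment: np.ndarray  # fold label per observation

    @property
    def n(self) -> int:
        return len(self.assignment)

    def test_indices(self, k: int) -> np.ndarray:
        if not 0 <= k < self.K:
            raise ValueError(f"fold {k} out of range for K={self.K}")
        return np.nonzero(self.assignment == k)[0]

    def train_indices(self, k: int) -> np.ndarray:
        if not 0 <= k < self.K:
            raise ValueError(f"fold {k} out of range for K={self.K}")
        return np.nonzero(self.assignment != k)[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.K)


def make_folds(n: int, K: int, rng: np.random.Generator) -> FoldPartition:
    """Assign n observations to K approximately equal, non-overlapping folds."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"cannot make {K} folds from {n} observations")
    labels = np.arange(n) % K
    assignment = labels[rng.permutation(n)]
    return FoldPartition(K=K, assignment=assignment)


@dataclass(frozen=True)
class WeightedTree:
    """One boosted tree with its vote weight, fold provenance and PIs."""

    tree: LogicTree
    alpha: float
    fold_id: int
    weighted_error: float
    pis: tuple[PrimeImplicant, ...]


@dataclass
class BoostedForest:
    """An LBoost model: K folds times A boosted trees."""

    trees: list[WeightedTree]
    partition: FoldPartition
    A: int
    max_size_cap: int
    schedule: AnnealSchedule
    seed: int | None = None
    _tree_sizes: list[int] = field(default_factory=list, repr=False)

    @property
    def K(self) -> int:
        return self.partition.K

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def fold_trees(self, k: int) -> list[WeightedTree]:
        out = [t for t in self.trees if t.fold_id == k]
        if not out:
            raise ValueError(f"no trees for fold {k}")
        return out


def _validate_binary(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match rows of X")
    if not np.isin(X, (0, 1)).all() or not np.isin(y, (0, 1)).all():
        raise ValueError("X and y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response is constant; nothing to classify")
    return X.astype(np.uint8), y.astype(np.uint8)


def fit_lboost(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 5,
    A: int = 20,
    max_size_cap: int = 8,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | int | None = None,
) -> BoostedForest:
    """Fit an LBoost model of K*A boosted logic trees.

    Per fold: initialize uniform weights on the training data, then for
    each of the A boosting rounds draw a tree-size cap S uniformly from
    {1, ..., max_size_cap} (random sizes modestly improve recovery of small
    interactions), anneal-fit a tree under the current weights, and update
    weights by the exponential reweighting described in the module
    docstring.  Prime implicants of each tree are extracted and stored.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X, y = _validate_binary(X, y)
    n = len(y)

    partition = make_folds(n, K, rng)
    trees: list[WeightedTree] = []
    sizes: list[int] = []
    for k in range(K):
        train = partition.train_indices(k)
        X_tr, y_tr = X[train], y[train]
        n_tr = len(train)
        eps = 1.0 / (2.0 * n_tr)
        w = np.full(n_tr, 1.0 / n_tr)
        for _ in range(A):
            S = int(rng.integers(1, max_size_cap + 1))
            sizes.append(S)
            tree = anneal_fit(X_tr, y_tr, w, S, schedule, rng)
            mis = evaluate_tree(tree, X_tr) != y_tr
            err = float(w[mis].sum())
            err_c = min(max(err, eps), 0.5 - eps)
            alpha = 0.5 * np.log((1.0 - err_c) / err_c)
            w = w * np.exp(alpha * np.where(mis, 1.0, -1.0))
            w /= w.sum()
            trees.append(
                WeightedTree(
                    tree=tree,
                    alpha=float(alpha),
                    fold_id=k,
                    weighted_error=err,
                    pis=tuple(
                        sorted(prime_implicants(tree), key=lambda pi: pi.key)
                    ),
                )
            )
    return BoostedForest(
        trees=trees,
        partition=partition,
        A=A,
        max_size_cap=max_size_cap,
        schedule=schedule,
        seed=seed,
        _tree_sizes=sizes,
    )


def _vote(trees: list[WeightedTree], X: np.ndarray) -> np.ndarray:
    vote = np.zeros(X.shape[0])
    for entry in trees:
        pred = evaluate_tree(entry.tree, X).astype(float)
        vote += entry.alpha * (2.0 * pred - 1.0)
    return vote


def cv_predict(forest: BoostedForest, k: int, X_test: np.ndarray) -> np.ndarray:
    """Weighted-vote prediction from the trees of fold k.

    The vote is sum of alpha * (2*yhat - 1) over that fold's trees — the
    0/1 tree predictions are mapped to +/-1 so every tree weight enters —
    and the class is 1 iff the vote is strictly positive (ties go to 0).
    """
    X_test = np.asarray(X_test)
    return (_vote(forest.fold_trees(k), X_test) > 0).astype(np.uint8)


def cv_misclassification(forest: BoostedForest, X: np.ndarray, y: np.ndarray) -> float:
    """Cross-validated misclassification rate over all n observations.

    Each observation is predicted by the fold in which it was held out,
    giving an unbiased estimate of model error.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) != forest.partition.n:
        warnings.warn("data size differs from the partition the forest was built on")
    wrong = 0
    for k in range(forest.K):
        test = forest.partition.test_indices(k)
        pred = cv_predict(forest, k, X[test])
        wrong += int((pred != y[test]).sum())
    return wrong / len(y)


def tree_cv_misclassification(
    entry: WeightedTree, forest: BoostedForest, X: np.ndarray, y: np.ndarray
) -> float:
    """Misclassification rate of one tree on its own fold's held-out data."""
    test = forest.partition.test_indices(entry.fold_id)
    pred = evaluate_tree(entry.tree, np.asarray(X)[test])
    return float((pred != np.asarray(y)[test]).mean())
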