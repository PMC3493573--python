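"""Model/Results front end, in the spirit of statsmodels estimators.

``LBoost`` and ``LogicForest`` are built from data (arrays, a
:class:`~lboost.data.BinaryDataset`, or a DataFrame via
``from_dataframe``); ``fit(seed=...)`` runs the ensemble search and
returns a results object carrying the fitted forest, cross-validated (or
out-of-bag) error, prime-implicant importance tables and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import boosting, forest as lf, importance as imp
from .annealing import AnnealSchedule
from .data import BinaryDataset
from .logic import evaluate_tree, parse_tree

__all__ = ["LBoost", "LBoostResults", "LogicForest", "LogicForestResults"]


class _BinaryModel:
    """Shared constructor plumbing for the two ensemble models."""

    def __init__(self, X, y=None):
        if isinstance(X, BinaryDataset):
            self.data = X
        else:
            if y is None:
                raise ValueError("y is required when X is an array")
            self.data = BinaryDataset(X, y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "y", **kwargs):
        return cls(BinaryDataset.from_dataframe(df, response=response), **kwargs)


class LBoost(_BinaryModel):
    """Boosted logic-regression ensemble with K-fold CV structure.

    Parameters
    ----------
    X, y : binary predictor matrix and response (or a BinaryDataset as X).
    n_folds : number of CV folds K (default 5).
    trees_per_fold : boosted trees A per fold (default 20; total K*A).
    max_tree_size : cap on leaves per tree, at most 8.
    schedule : annealing schedule for each tree fit.
    """

    def __init__(
        self,
        X,
        y=None,
        *,
        n_folds: int = 5,
        trees_per_fold: int = 20,
        max_tree_size: int = 8,
        schedule: AnnealSchedule | None = None,
    ):
        super().__init__(X, y)
        self.n_folds = n_folds
        self.trees_per_fold = trees_per_fold
        self.max_tree_size = max_tree_size
        self.schedule = schedule or AnnealSchedule()

    def fit(self, seed: int | np.random.Generator | None = None) -> "LBoostResults":
        forest = boosting.fit_lboost(
            self.data.X,
            self.data.y,
            K=self.n_folds,
            A=self.trees_per_fold,
            max_size_cap=self.max_tree_size,
            schedule=self.schedule,
            rng=seed,
        )
        return LBoostResults(self, forest)


class LBoostResults:
    """Fitted LBoost model: forest, CV error, importance, prediction."""

    def __init__(self, model: LBoost, forest: boosting.BoostedForest):
        self.model = model
        self.forest = forest

    @property
    def cv_misclassification_(self) -> float:
        return boosting.cv_misclassification(
            self.forest, self.model.data.X, self.model.data.y
        )

    def importance(
        self, seed: int | np.random.Generator | None = None, reps: int = 1
    ) -> pd.DataFrame:
        """Permutation PI-importance table (V.LB)."""
        return imp.v_lb(
            self.forest, self.model.data.X, self.model.data.y, rng=seed, reps=reps
        )

    def empirical_pvalue(
        self, pi_key: str, n_perm: int = 199, seed=None
    ) -> float:
        return imp.empirical_pvalue(
            self.forest, self.model.data.X, self.model.data.y, pi_key, n_perm, rng=seed
        )

    def predict(self, X) -> np.ndarray:
        """Class prediction for new data: alpha-weighted vote over all K*A trees."""
        X = np.asarray(X)
        return (boosting._vote(self.forest.trees, X) > 0).astype(np.uint8)

    def summary(self) -> str:
        f = self.forest
        alphas = np.array([t.alpha for t in f.trees])
        sizes = np.array([t.tree.n_leaves for t in f.trees])
        n_pis = len({pi.key for t in f.trees for pi in t.pis})
        lines = [
            "LBoost Results",
            "=" * 46,
            f"{'Observations':<30}{f.partition.n:>16}",
            f"{'Predictors':<30}{self.model.data.p:>16}",
            f"{'CV folds (K)':<30}{f.K:>16}",
            f"{'Trees per fold (A)':<30}{f.A:>16}",
            f"{'Total trees':<30}{f.n_trees:>16}",
            f"{'Max tree size':<30}{f.max_size_cap:>16}",
            f"{'CV misclassification':<30}{self.cv_misclassification_:>16.4f}",
            f"{'Mean tree weight (alpha)':<30}{alphas.mean():>16.4f}",
            f"{'Mean tree size (leaves)':<30}{sizes.mean():>16.2f}",
            f"{'Distinct prime implicants':<30}{n_pis:>16}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_importance(self, k: int = 20, seed=None, ax=None):
        """Horizontal bar chart of the top-k PIs by |V.LB|."""
        import matplotlib.pyplot as plt

        table = self.importance(seed=seed)
        top = imp.top_k_pis(table, k=k)
        sub = table.set_index("pi").loc[top]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(sub) + 1))
        ax.barh(sub.index[::-1], sub["importance"][::-1])
        ax.set_xlabel("V.LB (permutation importance)")
        return ax

    # -- persistence --------------------------------------------------------

    def to_json(self) -> dict:
        f = self.forest
        return {
            "type": "lboost",
            "K": f.K,
            "A": f.A,
            "max_size_cap": f.max_size_cap,
            "schedule": asdict(f.schedule),
            "seed": f.seed,
            "fold_assignment": f.partition.assignment.tolist(),
            "trees": [
                {
                    "tree": str(t.tree),
                    "alpha": t.alpha,
                    "fold": t.fold_id,
                    "weighted_error": t.weighted_error,
                }
                for t in f.trees
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path, data: BinaryDataset) -> "LBoostResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("type") != "lboost":
            raise ValueError("not an LBoost model file")
        from .boosting import BoostedForest, FoldPartition, WeightedTree
        from .logic import prime_implicants

        partition = FoldPartition(
            K=payload["K"], assignment=np.asarray(payload["fold_assignment"])
        )
        trees = []
        for t in payload["trees"]:
            tree = parse_tree(t["tree"])
            trees.append(
                WeightedTree(
                    tree=tree,
                    alpha=t["alpha"],
                    fold_id=t["fold"],
                    weighted_error=t["weighted_error"],
                    pis=tuple(sorted(prime_implicants(tree), key=lambda pi: pi.key)),
                )
            )
        forest = BoostedForest(
            trees=trees,
            partition=partition,
            A=payload["A"],
            max_size_cap=payload["max_size_cap"],
            schedule=AnnealSchedule(**payload["schedule"]),
            seed=payload.get("seed"),
        )
        model = LBoost(
            data,
            n_folds=payload["K"],
            trees_per_fold=payload["A"],
            max_tree_size=payload["max_size_cap"],
            schedule=forest.schedule,
        )
        return cls(model, forest)


class LogicForest(_BinaryModel):
    """Bagged logic-regression ensemble (the Logic Forest baseline)."""

    def __init__(
        self,
        X,
        y=None,
        *,
        n_trees: int = 100,
        max_tree_size: int = 8,
        schedule: AnnealSchedule | None = None,
    ):
        super().__init__(X, y)
        self.n_trees = n_trees
        self.max_tree_size = max_tree_size
        self.schedule = schedule or AnnealSchedule()

    def fit(self, seed: int | np.random.Generator | None = None) -> "LogicForestResults":
        bagged = lf.fit_logic_forest(
            self.data.X,
            self.data.y,
            B=self.n_trees,
            max_size_cap=self.max_tree_size,
            schedule=self.schedule,
            rng=seed,
        )
        return LogicForestResults(self, bagged)


class LogicForestResults:
    """Fitted Logic Forest: bagged trees, OOB error, V.LF importance."""

    def __init__(self, model: LogicForest, bagged: lf.BaggedForest):
        self.model = model
        self.bagged = bagged

    @property
    def oob_misclassification_(self) -> float:
        """Majority-vote OOB error over observations with at least one OOB tree."""
        X, y = self.model.data.X, self.model.data.y
        n = len(y)
        votes = np.zeros(n)
        counts = np.zeros(n)
        for entry in self.bagged.trees:
            idx = entry.oob_indices
            if len(idx) == 0:
                continue
            votes[idx] += evaluate_tree(entry.tree, X[idx])
            counts[idx] += 1
        mask = counts > 0
        pred = (votes[mask] / counts[mask] > 0.5).astype(np.uint8)
        return float((pred != y[mask]).mean())

    def importance(self) -> pd.DataFrame:
        """OOB-accuracy PI-importance table (V.LF)."""
        return lf.v_lf(self.bagged, self.model.data.X, self.model.data.y)

    def summary(self) -> str:
        sizes = np.array([t.tree.n_leaves for t in self.bagged.trees])
        n_pis = len({pi.key for t in self.bagged.trees for pi in t.pis})
        lines = [
            "Logic Forest Results",
            "=" * 46,
            f"{'Observations':<30}{self.model.data.n:>16}",
            f"{'Predictors':<30}{self.model.data.p:>16}",
            f"{'Trees (B)':<30}{self.bagged.B:>16}",
            f"{'Max tree size':<30}{self.bagged.max_size_cap:>16}",
            f"{'OOB misclassification':<30}{self.oob_misclassification_:>16.4f}",
            f"{'Mean tree size (leaves)':<30}{sizes.mean():>16.2f}",
            f"{'Distinct prime implicants':<30}{n_pis:>16}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "type": "logic_forest",
            "B": self.bagged.B,
            "max_size_cap": self.bagged.max_size_cap,
            "schedule": asdict(self.bagged.schedule),
            "seed": self.bagged.seed,
            "trees": [
                {"tree": str(t.tree), "oob": t.oob_indices.tolist()}
                for t in self.bagged.trees
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path, data: BinaryDataset) -> "LogicForestResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("type") != "logic_forest":
            raise ValueError("not a Logic Forest model file")
        from .logic import prime_implicants

        trees = []
        for t in payload["trees"]:
            tree = parse_tree(t["tree"])
            trees.append(
                lf.BaggedTree(
                    tree=tree,
                    oob_indices=np.asarray(t["oob"], dtype=int),
                    pis=tuple(sorted(prime_implicants(tree), key=lambda pi: pi.key)),
                )
            )
        bagged = lf.BaggedForest(
            trees=trees,
            max_size_cap=payload["max_size_cap"],
            schedule=AnnealSchedule(**payload["schedule"]),
            seed=payload.get("seed"),
        )
        model = LogicForest(
            data,
            n_trees=payload["B"],
            max_tree_size=payload["max_size_cap"],
            schedule=bagged.schedule,
        )
        return cls(model, bagged)
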