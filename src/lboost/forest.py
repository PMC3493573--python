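"""Logic Forest: the bagging baseline.

Each of B logic trees is anneal-fit on a bootstrap resample of the data
(uniform weights, random size cap), and carries the out-of-bag (OOB) index
set of its resample.  The importance V.LF of a prime implicant is the sum,
over trees containing it, of that tree's OOB predictive accuracy, divided
by B — so a PI is important when it appears in many accurate trees, which
is precisely why rare interactions rank poorly under bagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annealing import AnnealSchedule, anneal_fit
from .boosting import _validate_binary
from .logic import LogicTree, PrimeImplicant, evaluate_tree, prime_implicants

__all__ = ["BaggedTree", "BaggedForest", "fit_logic_forest", "v_lf"]


@dataclass(frozen=True)
class BaggedTree:
    tree: LogicTree
    oob_indices: np.ndarray
    pis: tuple[PrimeImplicant, ...]


@dataclass
class BaggedForest:
    trees: list[BaggedTree]
    max_size_cap: int
    schedule: AnnealSchedule
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.trees)


def fit_logic_forest(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 100,
    max_size_cap: int = 8,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | int | None = None,
) -> BaggedForest:
    """Fit a Logic Forest of B bagged logic trees.

    Per tree: bootstrap-sample n rows with replacement, draw a size cap S
    uniformly from {1, ..., max_size_cap}, anneal-fit with uniform weights
    on the resample (duplicate rows weighted by multiplicity), and record
    the OOB indices and the tree's prime implicants.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X, y = _validate_binary(X, y)
    n = len(y)

    trees: list[BaggedTree] = []
    for _ in range(B):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        counts = np.bincount(boot, minlength=n).astype(float)
        w = counts / counts.sum()
        S = int(rng.integers(1, max_size_cap + 1))
        tree = anneal_fit(X, y, w, S, schedule, rng)
        trees.append(
            BaggedTree(
                tree=tree,
                oob_indices=oob,
                pis=tuple(sorted(prime_implicants(tree), key=lambda pi: pi.key)),
            )
        )
    return BaggedForest(trees=trees, max_size_cap=max_size_cap, schedule=schedule, seed=seed)


def v_lf(forest: BaggedForest, X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Frequency-weighted OOB-accuracy importance table.

    V.LF of PI j = (1/B) * sum over trees containing j of (1 - OOB
    misclassification).  A tree with an empty OOB set contributes its
    in-bag accuracy instead, with a warning.  Values lie in [0, 1]; a PI in
    no tree is absent from the table.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for entry in forest.trees:
        idx = entry.oob_indices
        if len(idx) == 0:
            warnings.warn("tree has empty OOB set; using in-bag accuracy")
            idx = np.arange(len(y))
        acc = float((evaluate_tree(entry.tree, X[idx]) == y[idx]).mean())
        for pi in entry.pis:
            sums[pi.key] = sums.get(pi.key, 0.0) + acc
            counts[pi.key] = counts.get(pi.key, 0) + 1
    keys = sorted(sums)
    table = pd.DataFrame(
        {
            "pi": keys,
            "importance": [sums[k] / forest.B for k in keys],
            "n_trees": [counts[k] for k in keys],
        }
    )
    table.attrs["measure"] = "v_lf"
    return table
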