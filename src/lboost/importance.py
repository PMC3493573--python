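"""Permutation-based prime-implicant importance for LBoost models.

Each boosted tree is, on its own fold's held-out data, a disjunction of its
prime-implicant columns.  Permuting one PI's column and re-forming the OR
breaks any real association between that PI and the response while leaving
the rest of the tree intact; the rise in the tree's held-out
misclassification is that tree's evidence for the PI.  The importance
V.LB of a PI is the sum of these contributions over all trees containing
it, divided by the total number of trees in the forest — the same
frequency-weighted normalization as the bagging importance V.LF, so a PI
ranks highly when it is both repeatedly selected and predictive on
held-out data.  Larger positive values mean more important.

Empirical p-values use the same column-permutation null: the observed V.LB
is compared against replicate V.LB values recomputed under independent
fresh permutations, with an add-one correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .boosting import BoostedForest, WeightedTree
from .logic import PrimeImplicant, canonical_key

__all__ = [
    "pi_matrix",
    "v_lb",
    "top_k_pis",
    "recovered",
    "empirical_pvalue",
]


def pi_matrix(entry: WeightedTree, X_test: np.ndarray) -> np.ndarray:
    """0/1 matrix whose column j evaluates PI j of the tree on the test rows.

    The OR across columns reproduces the tree's prediction on those rows.
    A tree with no PIs (contradiction or tautology) yields a zero-column
    matrix, with a warning.
    """
    X_test = np.asarray(X_test)
    if not entry.pis:
        warnings.warn("tree has no prime implicants; empty PI matrix")
        return np.zeros((X_test.shape[0], 0), dtype=np.uint8)
    cols = [pi.evaluate(X_test).astype(np.uint8) for pi in entry.pis]
    return np.column_stack(cols)


def _tree_contributions(
    entry: WeightedTree,
    P: np.ndarray,
    y_test: np.ndarray,
    mc_t: float,
    reps: int,
    rng: np.random.Generator,
) -> list[float]:
    """Permuted-minus-baseline misclassification per PI column of one tree."""
    n_k, m = P.shape
    out = []
    for j in range(m):
        deltas = []
        for _ in range(reps):
            perm = rng.permutation(n_k)
            Pj = P.copy()
            Pj[:, j] = P[perm, j]
            pred = Pj.any(axis=1).astype(np.uint8)
            deltas.append(float((pred != y_test).mean()) - mc_t)
        out.append(float(np.mean(deltas)))
    return out


def v_lb(
    forest: BoostedForest,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | int | None = None,
    reps: int = 1,
) -> pd.DataFrame:
    """Permutation importance table for every PI appearing in the forest.

    Columns: ``pi`` (canonical key), ``importance`` (V.LB), ``n_trees``
    (number of trees containing the PI).  A PI never referenced by any tree
    is absent, not zero.  ``reps`` averages several independent
    permutations per (tree, PI) pair for variance reduction; the definition
    uses a single permutation.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(X)
    y = np.asarray(y)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for entry in forest.trees:
        if not entry.pis:
            continue
        test = forest.partition.test_indices(entry.fold_id)
        X_test, y_test = X[test], y[test]
        P = pi_matrix(entry, X_test)
        mc_t = float((P.any(axis=1).astype(np.uint8) != y_test).mean())
        contribs = _tree_contributions(entry, P, y_test, mc_t, reps, rng)
        for pi, c in zip(entry.pis, contribs):
            key = pi.key
            sums[key] = sums.get(key, 0.0) + c
            counts[key] = counts.get(key, 0) + 1
    keys = sorted(sums)
    total = forest.n_trees
    table = pd.DataFrame(
        {
            "pi": keys,
            "importance": [sums[k] / total for k in keys],
            "n_trees": [counts[k] for k in keys],
        }
    )
    table.attrs["measure"] = "v_lb"
    return table


def top_k_pis(tables: pd.DataFrame | list[pd.DataFrame], k: int = 20) -> list[str]:
    """The k PI keys with largest absolute importance.

    Twenty is the conventional cut for a 100-SNP panel: it is ~0.4% of the
    C(100,2) = 4950 possible two-locus pairs.  Ties break lexicographically
    on the key; with fewer than k PIs all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    frames = pd.concat(tables, ignore_index=True)
    # a PI listed in several tables keeps its largest absolute importance
    frames["abs_imp"] = frames["importance"].abs()
    best = frames.groupby("pi", as_index=False)["abs_imp"].max()
    best = best.sort_values(["abs_imp", "pi"], ascending=[False, True], kind="stable")
    return best["pi"].head(k).tolist()


def recovered(target_pi: PrimeImplicant | str, top: list[str]) -> bool:
    """True iff the target PI's canonical key appears in the top list."""
    key = target_pi if isinstance(target_pi, str) else canonical_key(target_pi)
    return key in top


def empirical_pvalue(
    forest: BoostedForest,
    X: np.ndarray,
    y: np.ndarray,
    pi_key: str,
    n_perm: int,
    rng: np.random.Generator | int | None = None,
) -> float:
    """One-sided permutation p-value for one PI's importance.

    p = (1 + #{replicates with V.LB* >= observed}) / (1 + n_perm).  The
    observed V.LB uses the PI's real columns; each null replicate first
    replaces the PI's column with an independent permutation of itself —
    severing any association with the response while preserving its
    marginal frequency — and recomputes V.LB on that broken column.  A PI
    whose columns are constant on every test set is unaffected by
    permutation and gets p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(X)
    y = np.asarray(y)

    # cache the (tree, column) pairs involving this PI
    involved = []
    for entry in forest.trees:
        for j, pi in enumerate(entry.pis):
            if pi.key == pi_key:
                test = forest.partition.test_indices(entry.fold_id)
                P = pi_matrix(entry, X[test])
                mc_t = float((P.any(axis=1).astype(np.uint8) != y[test]).mean())
                involved.append((P, y[test], mc_t, j))
    if not involved:
        raise ValueError(f"PI {pi_key!r} does not occur in the forest")

    def one_vlb(null: bool) -> float:
        contribs = []
        for P, y_test, mc_t, j in involved:
            base = P
            base_mc = mc_t
            if null:  # break the PI-response association first
                base = P.copy()
                base[:, j] = P[rng.permutation(P.shape[0]), j]
                base_mc = float((base.any(axis=1).astype(np.uint8) != y_test).mean())
            Pj = base.copy()
            Pj[:, j] = base[rng.permutation(base.shape[0]), j]
            pred = Pj.any(axis=1).astype(np.uint8)
            contribs.append(float((pred != y_test).mean()) - base_mc)
        return float(np.mean(contribs))

    observed = one_vlb(null=False)
    exceed = sum(one_vlb(null=True) >= observed for _ in range(n_perm))
    return (1 + exceed) / (1 + n_perm)
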