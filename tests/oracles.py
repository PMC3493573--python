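"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np

from lboost.logic import AND, OR, Literal, LogicTree, Op, evaluate_tree


def truth_table(tree: LogicTree) -> tuple[list[int], np.ndarray, np.ndarray]:
    """(variables, assignment matrix, function values) over the tree's variables."""
    variables = tree.variables()
    v = len(variables)
    assign = np.zeros((2**v, max(variables) + 1), dtype=np.uint8)
    for j, var in enumerate(variables):
        assign[:, var] = (np.arange(2**v) >> j) & 1
    return variables, assign, evaluate_tree(tree, assign).astype(bool)


def brute_force_prime_implicants(tree: LogicTree) -> set[frozenset[Literal]]:
    """All prime implicants by exhaustive enumeration of 3^v candidate conjunctions.

    A candidate assigns each variable absent / positive / negative.  It is an
    implicant when every assignment satisfying it satisfies the function, and
    prime when no single-literal deletion leaves an implicant (implication is
    monotone in literal addition, so single deletions suffice).  Degenerate
    functions (constant true or false) have no prime implicant of size >= 1.
    """
    variables, assign, f = truth_table(tree)
    v = len(variables)
    if f.all() or not f.any():
        return set()

    cols = {var: assign[:, var].astype(bool) for var in variables}

    def conj_mask(states: tuple[int, ...]) -> np.ndarray:
        mask = np.ones(len(f), dtype=bool)
        for var, s in zip(variables, states):
            if s == 1:
                mask &= cols[var]
            elif s == 2:
                mask &= ~cols[var]
        return mask

    def implies(states: tuple[int, ...]) -> bool:
        mask = conj_mask(states)
        return bool(np.all(f[mask])) if mask.any() else True

    out: set[frozenset[Literal]] = set()
    for states in product((0, 1, 2), repeat=v):
        if all(s == 0 for s in states):
            continue
        if not implies(states):
            continue
        prime = True
        for j, s in enumerate(states):
            if s == 0:
                continue
            dropped = states[:j] + (0,) + states[j + 1 :]
            if all(x == 0 for x in dropped):
                # empty conjunction implies f only for tautologies, excluded above
                continue
            if implies(dropped):
                prime = False
                break
        if prime:
            out.add(
                frozenset(
                    Literal(var, negated=(s == 2))
                    for var, s in zip(variables, states)
                    if s != 0
                )
            )
    return out


def all_trees_up_to_two_leaves(p: int):
    """Every logic tree with at most two leaves over p variables."""
    literals = [Literal(i, neg) for i in range(p) for neg in (False, True)]
    for lit in literals:
        yield LogicTree(lit)
    for op in (AND, OR):
        for a in literals:
            for b in literals:
                yield LogicTree(Op(op, a, b))


def best_two_leaf_score(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Global optimum of weighted misclassification over all <=2-leaf trees."""
    best = np.inf
    y = np.asarray(y)
    for tree in all_trees_up_to_two_leaves(X.shape[1]):
        pred = evaluate_tree(tree, X)
        score = float(w[pred != y].sum())
        best = min(best, score)
    return best
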