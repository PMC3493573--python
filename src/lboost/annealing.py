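"""Simulated-annealing search for a single logic-regression tree.

A tree is scored by its weighted misclassification of the binary response.
Internally the annealer works on the *count* scale (score = n times the
weighted misclassification, which for uniform weights is simply the number
of misclassified observations, the classic logic-regression convention).
Temperatures live on a log10 scale: the default schedule cools
geometrically from 10^2 — chosen so that roughly 90% of proposed moves are
accepted at the start — down to 10^-2, where almost no uphill move is
accepted, over 50,000 iterations.

The move set is the standard logic-regression neighborhood: replace a
leaf's variable, flip a leaf's complement, flip one AND/OR operator, grow a
leaf into a two-leaf branch, or prune a leaf away.  Moves that would
violate the size cap (at most ``max_size`` leaves, never more than 8) are
excluded from the draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .logic import AND, OR, Literal, LogicTree, Op, random_literal

__all__ = [
    "AnnealSchedule",
    "weighted_misclassification",
    "propose_move",
    "anneal_fit",
    "acceptance_rate",
]

MAX_TREE_SIZE = 8


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule on the log10 temperature scale."""

    start_temp_log10: float = 2.0
    end_temp_log10: float = -2.0
    n_iter: int = 50_000

    def __post_init__(self) -> None:
        if self.start_temp_log10 <= self.end_temp_log10:
            raise ValueError("start temperature must exceed end temperature")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    def temperatures(self) -> np.ndarray:
        return 10.0 ** np.linspace(
            self.start_temp_log10, self.end_temp_log10, self.n_iter
        )


def _check_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if np.any(w < 0):
        raise ValueError("observation weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("observation weights must sum to 1")
    return w


def weighted_misclassification(
    tree: LogicTree, X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> float:
    """Sum of weights over observations the tree misclassifies."""
    from .logic import evaluate_tree

    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("y length does not match number of rows of X")
    w = _check_weights(w, X.shape[0])
    pred = evaluate_tree(tree, X)
    return float(w[pred != y].sum())


# ---------------------------------------------------------------------------
# Move proposals
# ---------------------------------------------------------------------------

_MOVES = ("alt_leaf", "toggle_not", "alt_op", "grow", "prune")


def feasible_moves(tree: LogicTree, p: int, max_size: int) -> list[str]:
    n_leaves = tree.n_leaves
    moves = []
    if p >= 2:
        moves.append("alt_leaf")
    moves.append("toggle_not")
    if n_leaves >= 2:
        moves.append("alt_op")
    if n_leaves < max_size:
        moves.append("grow")
    if n_leaves >= 2:
        moves.append("prune")
    return moves


def propose_move(
    tree: LogicTree, p: int, max_size: int, rng: np.random.Generator
) -> LogicTree:
    """One random neighbor of the tree under the logic-regression move set."""
    if not 1 <= max_size <= MAX_TREE_SIZE:
        raise ValueError(f"max_size must be in [1, {MAX_TREE_SIZE}]")
    moves = feasible_moves(tree, p, max_size)
    move = moves[int(rng.integers(len(moves)))]
    leaves = tree.leaves()

    if move == "alt_leaf":
        path, lit = leaves[int(rng.integers(len(leaves)))]
        new_index = int(rng.integers(p - 1))
        if new_index >= lit.index:
            new_index += 1
        return tree.replace(path, Literal(new_index, bool(rng.integers(2))))

    if move == "toggle_not":
        path, lit = leaves[int(rng.integers(len(leaves)))]
        return tree.replace(path, lit.complement)

    if move == "alt_op":
        internal = tree.internal_nodes()
        path, node = internal[int(rng.integers(len(internal)))]
        flipped = Op(OR if node.op == AND else AND, node.left, node.right)
        return tree.replace(path, flipped)

    if move == "grow":
        path, lit = leaves[int(rng.integers(len(leaves)))]
        op = AND if rng.integers(2) else OR
        return tree.replace(path, Op(op, lit, random_literal(p, rng)))

    # prune: delete a leaf, promoting its sibling
    path, _ = leaves[int(rng.integers(len(leaves)))]
    parent_path, last = path[:-1], path[-1]
    node = tree.root
    for step in parent_path:
        node = node.left if step == 0 else node.right
    sibling = node.right if last == 0 else node.left
    return tree.replace(parent_path, sibling)


# ---------------------------------------------------------------------------
# Annealing engine
#
# The search state lives in a 1-based heap of at most 2^8 slots (a binary
# tree with <= 8 leaves never exceeds depth 7).  Node evaluations are
# bit-packed (one bit per observation) and only the path from a modified
# node to the root is recomputed after a move.  The weighted
# misclassification count is read off the packed root/response mismatch
# with per-byte lookup tables of weighted popcounts.
# ---------------------------------------------------------------------------

_EMPTY, _LEAF, _AND, _OR = 0, 1, 2, 3
_HEAP_CAP = 256
_BITS256 = ((np.arange(256)[:, None] >> (7 - np.arange(8)[None, :])) & 1).astype(
    float
)  # big-endian bit order of np.packbits


def _count_score(tree: LogicTree, X: np.ndarray, y: np.ndarray, sw: np.ndarray) -> float:
    from .logic import _eval_node

    pred = _eval_node(tree.root, X)
    return float(sw @ (pred != y))


class _BufferedRand:
    """Chunked uniform draws from a Generator, for cheap scalar sampling."""

    def __init__(self, rng: np.random.Generator, chunk: int = 65536):
        self._rng = rng
        self._chunk = chunk
        self._buf = rng.random(chunk)
        self._i = 0

    def uniform(self) -> float:
        if self._i == self._chunk:
            self._buf = self._rng.random(self._chunk)
            self._i = 0
        u = self._buf[self._i]
        self._i += 1
        return u

    def randint(self, k: int) -> int:
        return int(self.uniform() * k)


class _HeapAnnealer:
    """Mutable bit-packed tree state for the annealing chain.

    Node evaluations are Python integers used as n-bit masks (bit ops on
    them avoid per-call numpy overhead); the weighted misclassification
    count is read from the root/response mismatch via per-byte lookup
    tables of weighted popcounts.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, sw: np.ndarray, p: int):
        n = len(y)
        self.p = p
        self.nb = (n + 7) // 8
        pad = self.nb * 8 - n
        yp = np.concatenate([y.astype(bool), np.zeros(pad, dtype=bool)])
        self.y_int = int.from_bytes(np.packbits(yp).tobytes(), "big")
        cols = np.asarray(X, dtype=bool).T  # (p, n)
        padded = np.zeros((p, self.nb * 8), dtype=bool)
        padded[:, :n] = cols
        packed = np.packbits(padded, axis=1)
        self.col_pos = [int.from_bytes(row.tobytes(), "big") for row in packed]
        padded[:, :n] = ~cols
        padded[:, n:] = False  # padding bits carry zero weight either way
        packed = np.packbits(padded, axis=1)
        self.col_neg = [int.from_bytes(row.tobytes(), "big") for row in packed]
        w8 = np.zeros(self.nb * 8)
        w8[:n] = sw
        # weighted popcount lookup: wflat[pos * 256 + byte] = weight of set bits
        self.wflat = np.ascontiguousarray(
            (_BITS256 @ w8.reshape(self.nb, 8).T).T
        ).reshape(-1)
        self.base = np.arange(self.nb) * 256

        self.typ = [_EMPTY] * _HEAP_CAP
        self.var = [0] * _HEAP_CAP
        self.neg = [False] * _HEAP_CAP
        self.vals = [0] * _HEAP_CAP
        self.leaves: list[int] = []
        self.internal: list[int] = []

    # -- structure ----------------------------------------------------------

    def init_leaf(self, var: int, neg: bool) -> None:
        self.typ[1] = _LEAF
        self.var[1] = var
        self.neg[1] = neg
        self.vals[1] = self._leaf_val(var, neg)
        self.leaves = [1]
        self.internal = []

    def _leaf_val(self, var: int, neg: bool) -> int:
        return self.col_neg[var] if neg else self.col_pos[var]

    def _recompute(self, i: int) -> None:
        """Recompute packed values from node i up to the root."""
        typ, vals = self.typ, self.vals
        while i >= 1:
            t = typ[i]
            if t == _AND:
                vals[i] = vals[2 * i] & vals[2 * i + 1]
            elif t == _OR:
                vals[i] = vals[2 * i] | vals[2 * i + 1]
            else:
                vals[i] = self._leaf_val(self.var[i], self.neg[i])
            i //= 2

    def score(self) -> float:
        mis = self.vals[1] ^ self.y_int
        arr = np.frombuffer(mis.to_bytes(self.nb, "big"), dtype=np.uint8)
        return float(self.wflat[self.base + arr].sum())

    # -- conversion ---------------------------------------------------------

    def to_tree(self) -> LogicTree:
        def build(i: int):
            if self.typ[i] == _LEAF:
                return Literal(int(self.var[i]), bool(self.neg[i]))
            op = AND if self.typ[i] == _AND else OR
            return Op(op, build(2 * i), build(2 * i + 1))

        return LogicTree(build(1))

    def load_tree(self, tree: LogicTree) -> None:
        self.typ = [_EMPTY] * _HEAP_CAP
        self.leaves, self.internal = [], []

        def place(node, i: int) -> None:
            if isinstance(node, Literal):
                self.typ[i] = _LEAF
                self.var[i] = node.index
                self.neg[i] = node.negated
                self.vals[i] = self._leaf_val(node.index, node.negated)
                self.leaves.append(i)
            else:
                self.typ[i] = _AND if node.op == AND else _OR
                self.internal.append(i)
                place(node.left, 2 * i)
                place(node.right, 2 * i + 1)

        place(tree.root, 1)
        self._recompute_all()

    def _recompute_all(self) -> None:
        for i in sorted(self.internal, reverse=True):
            self._recompute_children_only(i)
        self._recompute(max(self.internal, default=1))

    def _recompute_children_only(self, i: int) -> None:
        t = self.typ[i]
        if t == _AND:
            self.vals[i] = self.vals[2 * i] & self.vals[2 * i + 1]
        elif t == _OR:
            self.vals[i] = self.vals[2 * i] | self.vals[2 * i + 1]

    def snapshot(self) -> tuple:
        idx = self.leaves + self.internal
        return (
            [(i, self.typ[i], self.var[i], self.neg[i]) for i in idx],
            list(self.leaves),
            list(self.internal),
        )

    def restore(self, snap: tuple) -> None:
        slots, leaves, internal = snap
        self.typ = [_EMPTY] * _HEAP_CAP
        for i, t, v, ng in slots:
            self.typ[i] = t
            self.var[i] = v
            self.neg[i] = ng
        self.leaves = list(leaves)
        self.internal = list(internal)
        for i in self.leaves:
            self.vals[i] = self._leaf_val(self.var[i], self.neg[i])
        for i in sorted(self.internal, reverse=True):
            self._recompute_children_only(i)

    # -- moves (mirror propose_move's distribution) --------------------------

    def feasible(self, max_size: int) -> list[str]:
        moves = []
        if self.p >= 2:
            moves.append("alt_leaf")
        moves.append("toggle_not")
        if len(self.leaves) >= 2:
            moves.append("alt_op")
        if len(self.leaves) < max_size:
            moves.append("grow")
        if len(self.leaves) >= 2:
            moves.append("prune")
        return moves

    def apply(self, move: str, rng: "_BufferedRand") -> tuple:
        """Apply one random instance of the move; return an undo token."""
        if move == "alt_leaf":
            i = self.leaves[rng.randint(len(self.leaves))]
            old = (int(self.var[i]), bool(self.neg[i]))
            new_index = rng.randint(self.p - 1)
            if new_index >= old[0]:
                new_index += 1
            self.var[i] = new_index
            self.neg[i] = rng.uniform() < 0.5
            self._recompute(i)
            return ("leafvar", i, old)

        if move == "toggle_not":
            i = self.leaves[rng.randint(len(self.leaves))]
            old = (int(self.var[i]), bool(self.neg[i]))
            self.neg[i] = not self.neg[i]
            self._recompute(i)
            return ("leafvar", i, old)

        if move == "alt_op":
            i = self.internal[rng.randint(len(self.internal))]
            self.typ[i] = _AND if self.typ[i] == _OR else _OR
            self._recompute(i)
            return ("op", i, None)

        if move == "grow":
            i = self.leaves[rng.randint(len(self.leaves))]
            old = (int(self.var[i]), bool(self.neg[i]))
            li, ri = 2 * i, 2 * i + 1
            self.typ[li] = _LEAF
            self.var[li] = old[0]
            self.neg[li] = old[1]
            self.vals[li] = self.vals[i]
            self.typ[ri] = _LEAF
            self.var[ri] = rng.randint(self.p)
            self.neg[ri] = rng.uniform() < 0.5
            self.vals[ri] = self._leaf_val(self.var[ri], self.neg[ri])
            self.typ[i] = _AND if rng.uniform() < 0.5 else _OR
            self.leaves.remove(i)
            self.leaves += [li, ri]
            self.internal.append(i)
            self._recompute(i)
            return ("ungrow", i, old)

        # prune: delete a random leaf, promoting its sibling subtree
        snap = self.snapshot()
        i = self.leaves[rng.randint(len(self.leaves))]
        parent, sib = i // 2, i ^ 1
        moved: list[tuple[int, int]] = []  # (src, dst) pairs, parents first
        stack = [(sib, parent)]
        while stack:
            src, dst = stack.pop()
            moved.append((src, dst))
            if self.typ[src] != _LEAF:
                stack.append((2 * src, 2 * dst))
                stack.append((2 * src + 1, 2 * dst + 1))
        old_slots = {s for s, _ in moved} | {i}
        new_slots = {d for _, d in moved}
        copies = {
            src: (self.typ[src], self.var[src], self.neg[src], self.vals[src])
            for src, _ in moved
        }
        for src, dst in moved:
            t, v, ng, val = copies[src]
            self.typ[dst] = t
            self.var[dst] = v
            self.neg[dst] = ng
            self.vals[dst] = val
        for s in old_slots - new_slots:
            self.typ[s] = _EMPTY
        self.leaves = [d for src, d in moved if copies[src][0] == _LEAF]
        self.internal = [d for src, d in moved if copies[src][0] != _LEAF]
        # re-attach the untouched remainder of the tree
        for s, t, v, ng in snap[0]:
            if self.typ[s] != _EMPTY and s not in new_slots and s != i:
                if t == _LEAF and s not in self.leaves:
                    self.leaves.append(s)
                elif t != _LEAF and s not in self.internal:
                    self.internal.append(s)
        self._recompute(parent)
        return ("snapshot", None, snap)

    def undo(self, token: tuple) -> None:
        kind, i, payload = token
        if kind == "leafvar":
            self.var[i], self.neg[i] = payload
            self._recompute(i)
        elif kind == "op":
            self.typ[i] = _AND if self.typ[i] == _OR else _OR
            self._recompute(i)
        elif kind == "ungrow":
            li, ri = 2 * i, 2 * i + 1
            self.typ[li] = _EMPTY
            self.typ[ri] = _EMPTY
            self.typ[i] = _LEAF
            self.var[i], self.neg[i] = payload
            self.leaves.remove(li)
            self.leaves.remove(ri)
            self.leaves.append(i)
            self.internal.remove(i)
            self._recompute(i)
        else:  # snapshot
            self.restore(payload)


def anneal_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    max_size: int,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | None = None,
) -> LogicTree:
    """Fit one logic tree by simulated annealing on weighted misclassification.

    Starts from a random single leaf and performs ``schedule.n_iter``
    proposals; downhill (and equal-score) moves are always accepted, uphill
    moves with probability exp(-delta/T) where delta is on the count scale.
    Returns the best-scoring tree visited during the run.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X)
    y = np.asarray(y).astype(bool)
    n, p = X.shape
    w = _check_weights(w, n)
    if not 1 <= max_size <= MAX_TREE_SIZE:
        raise ValueError(f"max_size must be in [1, {MAX_TREE_SIZE}]")
    if y.all() or not y.any():
        warnings.warn("response is constant; annealing result is degenerate")

    sw = w * n  # count scale: uniform weights -> misclassification counts
    state = _HeapAnnealer(X, y, sw, p)
    start = random_literal(p, rng)
    state.init_leaf(start.index, start.negated)
    cur_score = state.score()
    best_tree = state.to_tree()
    best_score = cur_score

    temps = schedule.temperatures()
    unif = rng.random(schedule.n_iter)
    rand = _BufferedRand(rng)
    for it in range(schedule.n_iter):
        moves = state.feasible(max_size)
        move = moves[rand.randint(len(moves))]
        token = state.apply(move, rand)
        new_score = state.score()
        delta = new_score - cur_score
        if delta <= 0 or unif[it] < math.exp(-delta / temps[it]):
            cur_score = new_score
            if cur_score < best_score - 1e-12:
                best_score = cur_score
                best_tree = state.to_tree()
        else:
            state.undo(token)
    return best_tree


def acceptance_rate(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    temp: float,
    n_proposals: int,
    max_size: int = MAX_TREE_SIZE,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical move-acceptance fraction of a constant-temperature chain.

    Used to calibrate the start temperature (about 90% acceptance at 10^2
    for misclassification-count score differences).
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X)
    y = np.asarray(y).astype(bool)
    n, p = X.shape
    w = _check_weights(w, n)
    Xb = np.asfortranarray(X, dtype=bool)
    sw = w * n

    current = LogicTree(random_literal(p, rng))
    cur_score = _count_score(current, Xb, y, sw)
    accepted = 0
    for _ in range(n_proposals):
        proposal = propose_move(current, p, max_size, rng)
        new_score = _count_score(proposal, Xb, y, sw)
        delta = new_score - cur_score
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            current, cur_score = proposal, new_score
            accepted += 1
    return accepted / n_proposals
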