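"""Boolean logic trees and prime implicants.

Logic-regression trees are strictly binary trees whose internal nodes carry
an AND (``&``) or OR (``|``) operator and whose leaves are possibly
complemented binary predictors (``X3``, ``!X7``).  Every such tree defines a
Boolean function of its leaf variables, which can always be rewritten as a
disjunction of conjunctions; the minimal conjunctions that imply the
function are its *prime implicants* (PIs) — the interpretable interaction
units of logic regression.  A PI like ``X1&X2`` reads "at least the
conditions X1 and X2 jointly hold".

Complement (NOT) is permitted on leaves only; trees never exceed eight
leaves, so truth-table work on a tree's variables is at most 2^8 rows and
prime-implicant extraction by Quine–McCluskey is always cheap.

Variables are referenced by 0-based column index into the predictor matrix
but rendered 1-based (column 0 is ``X1``), matching the usual SNP-table
labelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

import numpy as np

__all__ = [
    "Literal",
    "Op",
    "LogicTree",
    "PrimeImplicant",
    "evaluate_tree",
    "to_dnf",
    "prime_implicants",
    "canonical_key",
    "parse_implicant",
    "parse_tree",
    "random_tree",
]

AND = "&"
OR = "|"

_LIT_RE = re.compile(r"^(!?)X(\d+)$")


@dataclass(frozen=True, order=True)
class Literal:
    """A possibly complemented binary predictor: ``X5`` or ``!X5``."""

    index: int
    negated: bool = False

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"variable index must be non-negative, got {self.index}")

    @property
    def complement(self) -> "Literal":
        return Literal(self.index, not self.negated)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.index].astype(bool)
        return ~col if self.negated else col

    def __str__(self) -> str:
        return ("!" if self.negated else "") + f"X{self.index + 1}"


@dataclass(frozen=True)
class Op:
    """Internal AND/OR node with exactly two children."""

    op: str
    left: "Node"
    right: "Node"

    def __post_init__(self) -> None:
        if self.op not in (AND, OR):
            raise ValueError(f"operator must be '&' or '|', got {self.op!r}")

    def __str__(self) -> str:
        return f"({self.left} {self.op} {self.right})"


Node = Union[Literal, Op]


@dataclass(frozen=True)
class LogicTree:
    """A logic-regression tree: a binary AND/OR tree over literals."""

    root: Node

    def __str__(self) -> str:
        return str(self.root)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaves(self) -> list[tuple[tuple[int, ...], Literal]]:
        """All leaves as (path, literal); path is a tuple of 0/1 child steps."""
        cached = self.__dict__.get("_leaves")
        if cached is not None:
            return cached
        out: list[tuple[tuple[int, ...], Literal]] = []

        def walk(node: Node, path: tuple[int, ...]) -> None:
            if isinstance(node, Literal):
                out.append((path, node))
            else:
                walk(node.left, path + (0,))
                walk(node.right, path + (1,))

        walk(self.root, ())
        self.__dict__["_leaves"] = out  # immutable tree: safe to memoize
        return out

    def internal_nodes(self) -> list[tuple[tuple[int, ...], Op]]:
        cached = self.__dict__.get("_internal")
        if cached is not None:
            return cached
        out: list[tuple[tuple[int, ...], Op]] = []

        def walk(node: Node, path: tuple[int, ...]) -> None:
            if isinstance(node, Op):
                out.append((path, node))
                walk(node.left, path + (0,))
                walk(node.right, path + (1,))

        walk(self.root, ())
        self.__dict__["_internal"] = out
        return out

    def variables(self) -> list[int]:
        """Sorted distinct variable indices used by the tree."""
        return sorted({lit.index for _, lit in self.leaves()})

    def replace(self, path: tuple[int, ...], new: Node) -> "LogicTree":
        """Return a copy of the tree with the node at *path* replaced."""

        def rebuild(node: Node, path: tuple[int, ...]) -> Node:
            if not path:
                return new
            assert isinstance(node, Op)
            if path[0] == 0:
                return Op(node.op, rebuild(node.left, path[1:]), node.right)
            return Op(node.op, node.left, rebuild(node.right, path[1:]))

        return LogicTree(rebuild(self.root, path))


@dataclass(frozen=True)
class PrimeImplicant:
    """A canonical conjunction of literals (no variable appears twice)."""

    literals: frozenset[Literal]

    def __post_init__(self) -> None:
        if not self.literals:
            raise ValueError("a prime implicant must contain at least one literal")
        idx = [lit.index for lit in self.literals]
        if len(set(idx)) != len(idx):
            raise ValueError("contradictory or duplicated variable in prime implicant")

    @property
    def size(self) -> int:
        return len(self.literals)

    def sorted_literals(self) -> list[Literal]:
        return sorted(self.literals, key=lambda l: (l.index, l.negated))

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0], dtype=bool)
        for lit in self.literals:
            out &= lit.evaluate(X)
        return out

    @property
    def key(self) -> str:
        return canonical_key(self)

    def __str__(self) -> str:
        return self.key

    def __iter__(self) -> Iterator[Literal]:
        return iter(self.sorted_literals())


def canonical_key(pi: PrimeImplicant) -> str:
    """Deterministic string key: literals sorted by (index, complemented).

    Two PIs share a key iff they contain the same literal set, regardless of
    construction order; the key round-trips through :func:`parse_implicant`.
    """
    return "&".join(str(lit) for lit in pi.sorted_literals())


def parse_implicant(key: str) -> PrimeImplicant:
    lits = []
    for token in key.split("&"):
        m = _LIT_RE.match(token.strip())
        if m is None:
            raise ValueError(f"cannot parse literal {token!r}")
        lits.append(Literal(int(m.group(2)) - 1, m.group(1) == "!"))
    return PrimeImplicant(frozenset(lits))


def _max_index(node: Node) -> int:
    if isinstance(node, Literal):
        return node.index
    return max(_max_index(node.left), _max_index(node.right))


def _eval_node(node: Node, X: np.ndarray) -> np.ndarray:
    if isinstance(node, Literal):
        return node.evaluate(X)
    a = _eval_node(node.left, X)
    b = _eval_node(node.right, X)
    return (a & b) if node.op == AND else (a | b)


def evaluate_tree(tree: LogicTree, X: np.ndarray) -> np.ndarray:
    """Evaluate the tree's Boolean function on each row of a 0/1 matrix.

    Returns a 0/1 vector of length ``n``: entry ``i`` is 1 iff the tree's
    expression is true on row ``i`` (equivalently, iff at least one prime
    implicant of the tree holds on that row).
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    hi = _max_index(tree.root)
    if hi >= X.shape[1]:
        raise IndexError(
            f"tree references variable index {hi} but X has {X.shape[1]} columns"
        )
    return _eval_node(tree.root, X).astype(np.uint8)


# ---------------------------------------------------------------------------
# DNF and prime implicants
# ---------------------------------------------------------------------------

Conjunction = frozenset  # frozenset[Literal]


def _combine_and(left: set, right: set) -> set:
    out = set()
    for a in left:
        for b in right:
            merged = a | b
            # drop contradictions (x AND !x)
            idx_seen: dict[int, bool] = {}
            ok = True
            for lit in merged:
                if lit.index in idx_seen and idx_seen[lit.index] != lit.negated:
                    ok = False
                    break
                idx_seen[lit.index] = lit.negated
            if ok:
                out.add(frozenset(merged))
    return out


def to_dnf(tree: LogicTree) -> set[Conjunction]:
    """Expand the tree to a disjunction of conjunctions.

    Contradictory conjunctions (containing a variable and its complement)
    are removed; a contradictory tree yields the empty set.  The returned
    set evaluates identically to the tree on every assignment.
    """

    def walk(node: Node) -> set:
        if isinstance(node, Literal):
            return {frozenset({node})}
        left, right = walk(node.left), walk(node.right)
        if node.op == OR:
            return left | right
        return _combine_and(left, right)

    return walk(tree.root)


def _truth_table(tree: LogicTree) -> tuple[list[int], np.ndarray]:
    """Boolean function of the tree over its own variables.

    Returns (sorted variable indices, f) where f has length 2**v and row
    ``a`` encodes the assignment whose bit ``j`` (LSB = first variable)
    gives the value of variable ``vars[j]``.
    """
    variables = tree.variables()
    v = len(variables)
    assign = np.zeros((2**v, max(variables) + 1), dtype=np.uint8)
    for j, var in enumerate(variables):
        assign[:, var] = (np.arange(2**v) >> j) & 1
    return variables, evaluate_tree(tree, assign).astype(bool)


def _qm_prime_implicants(minterms: set[int], v: int) -> set[tuple[int, int]]:
    """All prime implicants of a Boolean function by Quine–McCluskey.

    Terms are (value, dontcare_mask) pairs over ``v`` bit positions.  Two
    terms with the same mask merge when their values differ in exactly one
    cared bit; terms that never merge are prime.
    """
    current = {(m, 0) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        terms = sorted(current)
        by_mask: dict[int, list[tuple[int, int]]] = {}
        for t in terms:
            by_mask.setdefault(t[1], []).append(t)
        for mask, group in by_mask.items():
            vals = {t[0] for t in group}
            for val in vals:
                for j in range(v):
                    bit = 1 << j
                    if mask & bit:
                        continue
                    if (val ^ bit) in vals and not (val & bit):
                        merged.add((val, mask | bit))
                        used.add((val, mask))
                        used.add((val ^ bit, mask))
        primes |= current - used
        current = merged
    return primes


def prime_implicants(tree: LogicTree) -> set[PrimeImplicant]:
    """All prime implicants of the tree's Boolean function.

    Computed by Quine–McCluskey over the truth table restricted to the
    tree's variables (at most 8, so at most 256 assignments).  The result is
    an antichain under literal-set inclusion whose disjunction equals the
    tree's function.  Degenerate trees — contradictions (never true) and
    tautologies (always true, whose only prime implicant is the empty
    conjunction) — yield the empty set.
    """
    variables, f = _truth_table(tree)
    v = len(variables)
    minterms = {int(a) for a in np.nonzero(f)[0]}
    if not minterms or len(minterms) == 2**v:
        return set()
    out: set[PrimeImplicant] = set()
    for val, mask in _qm_prime_implicants(minterms, v):
        lits = frozenset(
            Literal(variables[j], negated=not (val >> j) & 1)
            for j in range(v)
            if not (mask >> j) & 1
        )
        if lits:
            out.add(PrimeImplicant(lits))
    return out


# ---------------------------------------------------------------------------
# Parsing and random trees
# ---------------------------------------------------------------------------


def parse_tree(text: str) -> LogicTree:
    """Parse the human-readable serialization, e.g. ``"((X1 & !X2) | X7)"``."""
    tokens = re.findall(r"[()&|]|!?X\d+", text.replace(" ", ""))
    if "".join(tokens) != text.replace(" ", ""):
        raise ValueError(f"cannot tokenize tree expression {text!r}")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of expression")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            left = parse_node()
            op = tokens[pos]
            if op not in (AND, OR):
                raise ValueError(f"expected operator, got {op!r}")
            pos += 1
            right = parse_node()
            if tokens[pos] != ")":
                raise ValueError("expected ')'")
            pos += 1
            return Op(op, left, right)
        m = _LIT_RE.match(tok)
        if m is None:
            raise ValueError(f"unexpected token {tok!r}")
        pos += 1
        return Literal(int(m.group(2)) - 1, m.group(1) == "!")

    root = parse_node()
    if pos != len(tokens):
        raise ValueError("trailing tokens in tree expression")
    return LogicTree(root)


def random_literal(p: int, rng: np.random.Generator) -> Literal:
    return Literal(int(rng.integers(p)), bool(rng.integers(2)))


def random_tree(p: int, n_leaves: int, rng: np.random.Generator) -> LogicTree:
    """A uniform-ish random binary tree with the given number of leaves."""
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")

    def build(k: int) -> Node:
        if k == 1:
            return random_literal(p, rng)
        split = int(rng.integers(1, k))
        op = AND if rng.integers(2) else OR
        return Op(op, build(split), build(k - split))

    return LogicTree(build(n_leaves))
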