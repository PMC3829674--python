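"""Counting binary ranked resolutions of a ranked constraint tree.

A constraint tree is a *multifurcating* ranked tree: each interior node
declares a monophyletic group (its descendant leaves) and the ranking fixes
the time order of the groups' most recent common ancestors.  A binary ranked
tree *resolves* the constraint tree if the constraint tree embeds into it
preserving labels, ancestry and rank order.

Interior nodes are identified with their ranks ``1..k`` (root = 1).  The tree
is encoded by the tuple ``(n_1, ..., n_k, f)``: ``n_i`` is the number of leaf
children of node ``i`` and ``f`` maps each non-root interior node to its
parent, with ``f(i) < i``.  The number of resolutions ``Rʳ(n_1,...,n_k,f)``
depends only on this tuple, not on the leaf labels.

Two routes are provided: a memoized reference recursion on coordinate tuples
(decrement one coordinate per coalescence; absorb the deepest node when it is
reduced to a cherry), and a bottom-up dynamic program over *eligible tuples*
bounded by the lineage-count matrices ``m`` and ``M``, which visits each
eligible state once and runs in O(n^k) for fixed ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .exact import count_ranked

__all__ = [
    "ConstraintTree",
    "BoundsMatrices",
    "validate_constraint_tree",
    "bounds_matrices",
    "count_resolutions_naive",
    "count_resolutions",
]


@dataclass(frozen=True)
class ConstraintTree:
    """A multifurcating ranked constraint tree in tuple encoding.

    Parameters
    ----------
    leaf_counts:
        ``(n_1, ..., n_k)`` — leaf children per interior node, in rank order.
    parents:
        ``{i: f(i)}`` for ``i = 2..k`` with ``f(i) < i``; empty when ``k = 1``.
    """

    leaf_counts: tuple[int, ...]
    parents: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaf_counts", tuple(int(c) for c in self.leaf_counts))
        object.__setattr__(self, "parents", dict(self.parents))
        validate_constraint_tree(self)

    def __hash__(self) -> int:  # parents dict is never mutated after init
        return hash((self.leaf_counts, tuple(sorted(self.parents.items()))))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConstraintTree):
            return NotImplemented
        return self.leaf_counts == other.leaf_counts and self.parents == other.parents

    @property
    def k(self) -> int:
        """Number of interior nodes."""
        return len(self.leaf_counts)

    @property
    def n(self) -> int:
        """Total number of leaves."""
        return sum(self.leaf_counts)

    @property
    def interior_children(self) -> tuple[int, ...]:
        """``α_i = |{a : f(a) = i}|`` for ``i = 1..k`` (0-indexed tuple)."""
        alpha = [0] * self.k
        for child, parent in self.parents.items():
            alpha[parent - 1] += 1
        return tuple(alpha)


def validate_constraint_tree(ctree: ConstraintTree) -> ConstraintTree:
    """Check the tuple encoding and return the tree.

    Raises :class:`ValueError` if the parent map is not rank-decreasing, if
    some node has fewer than two children, or if the tree has fewer than two
    leaves.
    """
    k = len(ctree.leaf_counts)
    if k < 1:
        raise ValueError("constraint tree needs at least one interior node")
    if any(c < 0 for c in ctree.leaf_counts):
        raise ValueError(f"negative leaf count in {ctree.leaf_counts}")
    expected = set(range(2, k + 1))
    if set(ctree.parents) != expected:
        raise ValueError(
            f"parent map must cover exactly nodes 2..{k}, got {sorted(ctree.parents)}"
        )
    for child, parent in ctree.parents.items():
        if not 1 <= parent < child:
            raise ValueError(f"rank order violated: f({child}) = {parent} must be < {child}")
    alpha = [0] * k
    for child, parent in ctree.parents.items():
        alpha[parent - 1] += 1
    for i in range(k):
        if ctree.leaf_counts[i] + alpha[i] < 2:
            raise ValueError(
                f"not multifurcated: node {i + 1} has "
                f"{ctree.leaf_counts[i] + alpha[i]} child(ren), needs >= 2"
            )
    if sum(ctree.leaf_counts) < 2:
        raise ValueError("constraint tree needs at least two leaves")
    return ctree


@dataclass(frozen=True)
class BoundsMatrices:
    """Lineage-count bounds for the eligible-tuple dynamic program.

    For a horizontal line drawn between the rank-``j`` and rank-``j+1``
    coalescence events of a resolving tree, ``m[i][j]`` and ``M[i][j]`` are
    the minimal and maximal numbers of branches of subtree ``i`` crossing the
    line (1-based ``i <= j <= k``; entries below the diagonal are ``None``).
    With ``a[i][j] = |{x <= j : f(x) = i}|`` (interior children of ``i``
    already present at level ``j``):

        M_{i,j} = n_i + α_i − a_{i,j}
        m_{i,j} = 2 if a_{i,j} = 0; 1 if a_{i,j} > 0 and M_{i,j} > 0; else 0.
    """

    a: tuple[tuple[int | None, ...], ...]
    lower: tuple[tuple[int | None, ...], ...]
    upper: tuple[tuple[int | None, ...], ...]

    def entry(self, which: str, i: int, j: int) -> int:
        """1-based access to ``a``, ``m`` (lower) or ``M`` (upper)."""
        mat = {"a": self.a, "m": self.lower, "M": self.upper}[which]
        val = mat[i - 1][j - 1]
        if val is None:
            raise ValueError(f"entry ({i},{j}) is below the diagonal")
        return val


def bounds_matrices(ctree: ConstraintTree) -> BoundsMatrices:
    """Compute the matrices ``a``, ``m`` and ``M`` for a constraint tree."""
    k = ctree.k
    alpha = ctree.interior_children
    a: list[list[int | None]] = [[None] * k for _ in range(k)]
    lower: list[list[int | None]] = [[None] * k for _ in range(k)]
    upper: list[list[int | None]] = [[None] * k for _ in range(k)]
    for i in range(1, k + 1):
        count = 0
        for j in range(1, k + 1):
            if ctree.parents.get(j) == i:
                count += 1
            if j < i:
                continue
            big = ctree.leaf_counts[i - 1] + alpha[i - 1] - count
            a[i - 1][j - 1] = count
            upper[i - 1][j - 1] = big
            if count == 0:
                lower[i - 1][j - 1] = 2
            elif big > 0:
                lower[i - 1][j - 1] = 1
            else:
                lower[i - 1][j - 1] = 0
    tup = lambda rows: tuple(tuple(r) for r in rows)
    return BoundsMatrices(a=tup(a), lower=tup(lower), upper=tup(upper))


# ---------------------------------------------------------------------------
# Reference recursion
# ---------------------------------------------------------------------------

def count_resolutions_naive(ctree: ConstraintTree) -> int:
    """Count ranked resolutions by the memoized coordinate recursion.

    States are tuples ``(x_1, ..., x_t)`` of unresolved lineage counts for the
    first ``t`` interior nodes (the parent map restricted accordingly).  The
    deepest coalescence of a resolving tree either merges two of the ``x_i``
    lineages of a candidate subtree (``C(x_i, 2)`` choices), or — when the
    deepest node has been reduced to exactly its own cherry — is that node
    itself, absorbing it into its parent as a single lineage.
    """
    parents = ctree.parents
    memo: dict[tuple[int, ...], int] = {}

    def rec(x: tuple[int, ...]) -> int:
        t = len(x)
        if t == 1:
            if x[0] == 2:
                return 1
            if x[0] < 2:
                return 0
        cached = memo.get(x)
        if cached is not None:
            return cached
        alpha = [0] * t
        for child in range(2, t + 1):
            alpha[parents[child] - 1] += 1
        total = 0
        for i in range(t):
            # candidate set C evaluated on the current tuple: node i+1 must
            # still hold >= 2 free lineages and have > 2 children in all
            if x[i] >= 2 and x[i] + alpha[i] > 2:
                total += (x[i] * (x[i] - 1) // 2) * rec(x[:i] + (x[i] - 1,) + x[i + 1:])
        if t >= 2 and x[t - 1] == 2:
            # node t is a cherry: it may itself be the deepest coalescence,
            # after which it is one lineage of its parent's subtree
            parent = parents[t]
            merged = list(x[: t - 1])
            merged[parent - 1] += 1
            total += rec(tuple(merged))
        memo[x] = total
        return total

    return rec(ctree.leaf_counts)


# ---------------------------------------------------------------------------
# Eligible-tuple dynamic program
# ---------------------------------------------------------------------------

def count_resolutions(ctree: ConstraintTree) -> int:
    """Count ranked resolutions by dynamic programming over eligible tuples.

    A tuple ``(x_1, ..., x_t)`` is *eligible* if ``m[i][t] <= x_i <= M[i][t]``
    for all ``i``.  Eligible tuples are enumerated outright, sorted by their
    coordinate sum ``s`` (each transition lowers ``s`` by one), and evaluated
    bottom-up with the same transition structure as the reference recursion;
    lookups of ineligible states contribute zero.  Each eligible tuple is
    visited exactly once.
    """
    bounds = bounds_matrices(ctree)
    parents = ctree.parents
    k = ctree.k
    values: dict[tuple[int, ...], int] = {}

    states: list[tuple[int, tuple[int, ...]]] = []
    for t in range(1, k + 1):
        ranges = [
            range(bounds.lower[i][t - 1], bounds.upper[i][t - 1] + 1)  # type: ignore[arg-type]
            for i in range(t)
        ]
        for x in product(*ranges):
            states.append((sum(x), x))
    states.sort(key=lambda item: (item[0], len(item[1])))

    alphas = [None] * (k + 1)
    for t in range(1, k + 1):
        al = [0] * t
        for child in range(2, t + 1):
            al[parents[child] - 1] += 1
        alphas[t] = al  # type: ignore[assignment]

    for _, x in states:
        t = len(x)
        if t == 1 and x[0] == 2:
            values[x] = 1
            continue
        alpha = alphas[t]
        total = 0
        for i in range(t):
            if x[i] >= 2 and x[i] + alpha[i] > 2:  # type: ignore[index]
                prev = values.get(x[:i] + (x[i] - 1,) + x[i + 1:], 0)
                total += (x[i] * (x[i] - 1) // 2) * prev
        if t >= 2 and x[t - 1] == 2:
            merged = list(x[: t - 1])
            merged[parents[t] - 1] += 1
            total += values.get(tuple(merged), 0)
        values[x] = total

    result = values.get(ctree.leaf_counts)
    if result is None:
        raise RuntimeError("internal error: root state not eligible")
    if not 1 <= result <= count_ranked(ctree.n):
        raise RuntimeError("internal error: resolution count out of range")
    return result
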