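"""Counting fully ranked resolutions of a fully ranked constraint tree.

A fully ranked constraint tree is a multifurcating tree whose interior nodes
*and* leaves are ranked on ``l`` levels (leaves may share a level, interior
nodes may not).  It encodes monophyly constraints plus a time order over both
clade ancestors and sampling times.  A fully ranked (binary) tree *resolves*
it if the constraint tree embeds preserving labels, ancestry, rank order and
rank-equality classes.

Encoding: interior nodes are numbered ``1..k`` in rank order, ``r(i)`` is the
level of node ``i`` (``r(1) = 1``), and the *child matrix* ``n`` of size
``k × l`` holds ``n[i][j]`` = number of children of node ``i`` with rank
``j`` — leaf children at leaf levels and, for each interior child ``c``, a 1
at column ``r(c)``.  ``N_{c,x} = Σ_{j>=x} n[c][j]`` counts children of ``c``
at level ``x`` or deeper.

Both a memoized reference recursion and a bottom-up dynamic program over
eligible matrix-tuples (keyed by active node count ``t``, level count ``q``
and the last matrix column) are provided; they agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

__all__ = [
    "FRConstraintTree",
    "validate_fr_constraint_tree",
    "fr_bounds_matrices",
    "candidate_set",
    "reduce_leaf",
    "merge_last_node",
    "count_fr_resolutions_naive",
    "count_fr_resolutions",
]

Matrix = tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class FRConstraintTree:
    """A fully ranked constraint tree.

    Parameters
    ----------
    ranks:
        ``(r(1), ..., r(k))``, strictly increasing, ``r(1) = 1``.
    leaf_matrix:
        ``k × l`` matrix of *leaf* children only: ``leaf_matrix[i][j]`` is the
        number of leaf children of interior node ``i+1`` with rank ``j+1``.
        Entries for interior children are derived from ``parents`` and
        ``ranks`` and added internally (see :attr:`child_matrix`).
    parents:
        ``{i: f(i)}`` for interior nodes ``i = 2..k``, ``f(i) < i``.
    """

    ranks: tuple[int, ...]
    leaf_matrix: Matrix
    parents: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", tuple(int(r) for r in self.ranks))
        object.__setattr__(
            self, "leaf_matrix", tuple(tuple(int(v) for v in row) for row in self.leaf_matrix)
        )
        object.__setattr__(self, "parents", dict(self.parents))
        validate_fr_constraint_tree(self)

    def __hash__(self) -> int:
        return hash((self.ranks, self.leaf_matrix, tuple(sorted(self.parents.items()))))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FRConstraintTree):
            return NotImplemented
        return (
            self.ranks == other.ranks
            and self.leaf_matrix == other.leaf_matrix
            and self.parents == other.parents
        )

    @property
    def k(self) -> int:
        """Number of interior nodes."""
        return len(self.ranks)

    @property
    def l(self) -> int:
        """Number of rank levels."""
        return len(self.leaf_matrix[0])

    @property
    def n(self) -> int:
        """Total number of leaves."""
        return sum(sum(row) for row in self.leaf_matrix)

    @property
    def child_matrix(self) -> Matrix:
        """``k × l`` matrix counting *all* children of each node per level."""
        rows = [list(row) for row in self.leaf_matrix]
        for child, parent in self.parents.items():
            rows[parent - 1][self.ranks[child - 1] - 1] += 1
        return tuple(tuple(row) for row in rows)

    def children_at_or_below(self, c: int, x: int) -> int:
        """``N_{c,x}``: number of children of node ``c`` with rank >= ``x`` (1-based)."""
        row = self.child_matrix[c - 1]
        return sum(row[x - 1:])


def validate_fr_constraint_tree(tree: FRConstraintTree) -> FRConstraintTree:
    """Check structural consistency; raises :class:`ValueError` on violation."""
    k = len(tree.ranks)
    if k < 1:
        raise ValueError("need at least one interior node")
    if tree.ranks[0] != 1:
        raise ValueError(f"the root must have rank 1, got r(1) = {tree.ranks[0]}")
    if any(b <= a for a, b in zip(tree.ranks, tree.ranks[1:])):
        raise ValueError(f"interior ranks must be strictly increasing, got {tree.ranks}")
    if len(tree.leaf_matrix) != k:
        raise ValueError(f"leaf matrix has {len(tree.leaf_matrix)} rows, expected k = {k}")
    widths = {len(row) for row in tree.leaf_matrix}
    if len(widths) != 1:
        raise ValueError("ragged leaf matrix")
    l = widths.pop()
    if tree.ranks[-1] >= l:
        raise ValueError(f"the deepest interior rank r(k) = {tree.ranks[-1]} must be < l = {l}")
    if set(tree.parents) != set(range(2, k + 1)):
        raise ValueError(
            f"parent map must cover exactly nodes 2..{k}, got {sorted(tree.parents)}"
        )
    for child, parent in tree.parents.items():
        if not 1 <= parent < child:
            raise ValueError(f"rank order violated: f({child}) = {parent} must be < {child}")
    interior_levels = set(tree.ranks)
    for i in range(k):
        for j in range(l):
            v = tree.leaf_matrix[i][j]
            if v < 0:
                raise ValueError("negative leaf count")
            if v and (j + 1) in interior_levels:
                raise ValueError(
                    f"leaves may not share level {j + 1} with an interior node"
                )
            if v and (j + 1) <= tree.ranks[i]:
                raise ValueError(
                    f"leaf child of node {i + 1} at level {j + 1} does not lie below "
                    f"its parent (rank {tree.ranks[i]})"
                )
    # every level occupied: interior levels by nodes, the rest by >= 1 leaf
    for j in range(1, l + 1):
        if j in interior_levels:
            continue
        if not any(tree.leaf_matrix[i][j - 1] for i in range(k)):
            raise ValueError(f"level {j} is empty")
    child = tree.child_matrix
    for i in range(k):
        if sum(child[i]) < 2:
            raise ValueError(f"node {i + 1} has {sum(child[i])} child(ren), needs >= 2")
    return tree


# ---------------------------------------------------------------------------
# Structural moves of the recursion
# ---------------------------------------------------------------------------

def candidate_set(tree: FRConstraintTree, p: int) -> set[int]:
    """``Cᵖ``: subtrees that can host the deepest coalescence at level ``p``.

    ``Cᵖ = {c : N_{c,p} >= 2 and N_{c,r(c)+1} > 2}`` — subtree ``c`` must have
    at least two lineages reaching level ``p`` and more than two children in
    total, for ``r(k) < p <= l``.
    """
    if not tree.ranks[-1] < p <= tree.l:
        raise ValueError(f"level p = {p} out of range ({tree.ranks[-1]} < p <= {tree.l})")
    out = set()
    for c in range(1, tree.k + 1):
        if (
            tree.children_at_or_below(c, p) >= 2
            and tree.children_at_or_below(c, tree.ranks[c - 1] + 1) > 2
        ):
            out.add(c)
    return out


def _reduced_matrix(child: Matrix, c: int, p: int) -> Matrix:
    """Child matrix after coalescing two of subtree ``c``'s lineages at level ``p``."""
    rows = []
    for i, row in enumerate(child, start=1):
        tail = sum(row[p - 1:])
        if i == c:
            tail -= 1
        rows.append(row[: p - 1] + (tail,))
    return tuple(rows)


def _merged_matrix(child: Matrix, rk: int) -> Matrix:
    """Child matrix after the deepest node (a cherry) becomes a leaf of its parent."""
    rows = []
    for row in child[:-1]:
        rows.append(row[: rk - 1] + (sum(row[rk - 1:]),))
    return tuple(rows)


def _matrix_to_tree(matrix: Matrix, ranks: tuple[int, ...], parents: dict[int, int]) -> FRConstraintTree:
    rows = [list(row) for row in matrix]
    for ch, parent in parents.items():
        rows[parent - 1][ranks[ch - 1] - 1] -= 1
    return FRConstraintTree(
        ranks=ranks, leaf_matrix=tuple(tuple(r) for r in rows), parents=parents
    )


def reduce_leaf(tree: FRConstraintTree, c: int, p: int) -> FRConstraintTree:
    """The constraint tree whose resolutions have the deepest coalescence in
    subtree ``c`` at level ``p``: levels >= ``p`` collapse into level ``p``
    and subtree ``c`` loses one lineage there."""
    if c not in candidate_set(tree, p):
        raise ValueError(f"subtree {c} is not a candidate at level {p}")
    return _matrix_to_tree(_reduced_matrix(tree.child_matrix, c, p), tree.ranks, tree.parents)


def merge_last_node(tree: FRConstraintTree) -> FRConstraintTree:
    """Absorb the deepest interior node (which must be a cherry) into its parent."""
    if tree.k < 2:
        raise ValueError("merge_last_node needs k >= 2 (the root cannot be absorbed)")
    if tree.children_at_or_below(tree.k, tree.ranks[-1] + 1) != 2:
        raise ValueError(f"node {tree.k} must have exactly 2 children")
    merged = _merged_matrix(tree.child_matrix, tree.ranks[-1])
    return _matrix_to_tree(
        merged, tree.ranks[:-1], {i: p for i, p in tree.parents.items() if i < tree.k}
    )


# ---------------------------------------------------------------------------
# Reference recursion
# ---------------------------------------------------------------------------

def count_fr_resolutions_naive(tree: FRConstraintTree) -> int:
    """Count fully ranked resolutions by the memoized matrix recursion.

    ``Fʳ(n, r) = Σ_{p=r(k)+1}^{l} Σ_{c∈Cᵖ} C(N_{c,p}, 2) Fʳ(n^{c,p}, r)
    [+ Fʳ(n', r|_{k-1}) when node k has exactly 2 children]`` with the
    two-leaf base ``Fʳ = 1``.
    """
    memo: dict[tuple[Matrix, tuple[int, ...]], int] = {}

    def rec(matrix: Matrix, ranks: tuple[int, ...]) -> int:
        k = len(matrix)
        if k == 1 and sum(matrix[0]) == 2:
            return 1
        key = (matrix, ranks)
        cached = memo.get(key)
        if cached is not None:
            return cached
        l = len(matrix[0])
        totals = [sum(row) for row in matrix]
        suffix = [list(row) for row in matrix]  # suffix[c][x-1] built below
        for c in range(k):
            acc = 0
            for x in range(l - 1, -1, -1):
                acc += matrix[c][x]
                suffix[c][x] = acc
        total = 0
        for p in range(ranks[-1] + 1, l + 1):
            for c in range(1, k + 1):
                ncp = suffix[c - 1][p - 1]
                if ncp >= 2 and totals[c - 1] > 2:
                    total += (ncp * (ncp - 1) // 2) * rec(
                        _reduced_matrix(matrix, c, p), ranks
                    )
        if k >= 2 and totals[k - 1] == 2:
            total += rec(_merged_matrix(matrix, ranks[-1]), ranks[:-1])
        memo[key] = total
        return total

    return rec(tree.child_matrix, tree.ranks)


# ---------------------------------------------------------------------------
# Eligible-tuple dynamic program
# ---------------------------------------------------------------------------

def fr_bounds_matrices(tree: FRConstraintTree) -> tuple[Matrix, Matrix]:
    """Lower/upper bounds ``(m, M)`` on per-subtree lineage counts per level.

    ``M[i][j] = N_{i,j+1}`` (nothing coalesced yet).  The lower bound is
    ``m[i][j] = max(0, 2 − c_{i,j})`` where ``c_{i,j}`` counts the children of
    node ``i`` (leaf or interior) with rank <= ``j``: a subtree state with
    fewer lineages than that would leave node ``i`` with fewer than two
    children and resolves to nothing.  For trees whose leaves all sit at the
    deepest level this coincides with the classical three-case rule driven by
    interior children only; with interleaved leaf ranks the leaf terms are
    required (see the package methods notes).  Entries are indexed
    ``m[i-1][j-1]`` for ``1 <= i <= k``, ``1 <= j <= l-1``.
    """
    child = tree.child_matrix
    k, l = tree.k, tree.l
    lower = []
    upper = []
    for i in range(k):
        row_lower = []
        row_upper = []
        seen = 0
        tail = sum(child[i])
        for j in range(1, l):
            seen += child[i][j - 1]
            tail_next = tail - seen  # N_{i,j+1}
            row_upper.append(tail_next)
            row_lower.append(max(0, 2 - seen))
        lower.append(tuple(row_lower))
        upper.append(tuple(row_upper))
    return tuple(lower), tuple(upper)


def count_fr_resolutions(tree: FRConstraintTree) -> int:
    """Count fully ranked resolutions by DP over eligible matrix-tuples.

    An intermediate tree with ``t`` active interior nodes and ``q`` levels
    agrees with the constraint matrix on all columns before ``q``; its state
    is therefore keyed by ``(t, q, last column)``.  The last column is bounded
    by the level-``q-1`` bounds matrices, eligible states are enumerated
    outright, sorted by matrix sum (each recursion move lowers it), and
    evaluated bottom-up with the recursion of
    :func:`count_fr_resolutions_naive`.  Each eligible state is visited once.
    """
    child = tree.child_matrix
    ranks = tree.ranks
    k, l = tree.k, tree.l
    lower, upper = fr_bounds_matrices(tree)
    # prefix[i][j] = number of children of node i+1 with rank <= j (0..l)
    prefix = []
    for i in range(k):
        acc = [0]
        for j in range(l):
            acc.append(acc[-1] + child[i][j])
        prefix.append(tuple(acc))

    values: dict[tuple[int, int, tuple[int, ...]], int] = {}
    states: list[tuple[int, int, int, tuple[int, ...]]] = []
    for t in range(1, k + 1):
        q_top = ranks[t] if t < k else l
        for q in range(ranks[t - 1] + 1, q_top + 1):
            base_sum = sum(prefix[i][q - 1] for i in range(t))
            col_ranges = [range(lower[i][q - 2], upper[i][q - 2] + 1) for i in range(t)]
            for col in product(*col_ranges):
                states.append((base_sum + sum(col), t, q, col))
    states.sort(key=lambda s: (s[0], s[1], s[2]))

    for total_sum, t, q, col in states:
        rowsums = [prefix[i][q - 1] + col[i] for i in range(t)]
        if t == 1 and rowsums[0] == 2:
            values[(t, q, col)] = 1
            continue
        total = 0
        for p in range(ranks[t - 1] + 1, q + 1):
            # N^x_{i,p} for the state matrix: constraint columns p..q-1 plus col
            nxp = [prefix[i][q - 1] - prefix[i][p - 1] + col[i] for i in range(t)]
            for c in range(t):
                if nxp[c] >= 2 and rowsums[c] > 2:
                    newcol = tuple(v - 1 if i == c else v for i, v in enumerate(nxp))
                    total += (nxp[c] * (nxp[c] - 1) // 2) * values.get((t, p, newcol), 0)
        if t >= 2 and rowsums[t - 1] == 2:
            rk = ranks[t - 1]
            newcol = tuple(
                prefix[i][q - 1] - prefix[i][rk - 1] + col[i] for i in range(t - 1)
            )
            total += values.get((t - 1, rk, newcol), 0)
        values[(t, q, col)] = total

    root_col = tuple(child[i][l - 1] for i in range(k))
    result = values.get((k, l, root_col))
    if result is None:
        raise RuntimeError("internal error: full-tree state not eligible")
    return result
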