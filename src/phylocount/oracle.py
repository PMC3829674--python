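"""Exhaustive enumeration of small tree spaces, for ground truth.

The counting recursions in this package are verified against literal
enumeration of every tree in the relevant space.  Trees are represented as
canonical nested tuples, so that Python set semantics give isomorphism-free
collections without any graph machinery:

* ranked tree:        ``("L", label)`` / ``("I", rank, left, right)``
* fully ranked tree:  ``("L", label, rank)`` / ``("I", rank, left, right)``
* FRS tree: as fully ranked, plus ``("A", label, rank, child)`` for a sampled
  ancestor sitting on a lineage (a degree-2 node, or the degree-1 root when it
  is the tree's top node).

Children of every interior node are stored in sorted order, ranks are
explicit, and labels are strings; two trees are isomorphic in the relevant
sense iff their tuples are equal.  Enumeration is by backward coalescence:
walking back in time, each step either merges one unordered pair of active
lineages or introduces a sampling time; every tree arises from exactly one
choice sequence, and the results are deduplicated defensively anyway.

These generators are exponential by design and refuse inputs above a small
cap unless ``allow_large=True``.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

from .constraints import ConstraintTree
from .fr_constraints import FRConstraintTree

__all__ = [
    "enumerate_ranked",
    "enumerate_fully_ranked",
    "enumerate_frs",
    "enumerate_resolutions",
    "enumerate_resolutions_constructive",
    "enumerate_fr_resolutions",
    "pre_ranking",
    "tree_leaf_ranks",
    "clade_rank_map",
]

RANKED_CAP = 7
FRS_CAP = 6


def _check_cap(n: int, cap: int, allow_large: bool, what: str) -> None:
    if n > cap and not allow_large:
        raise ValueError(
            f"refusing to enumerate {what} with n = {n} > cap {cap}; "
            "pass allow_large=True to override"
        )


# ---------------------------------------------------------------------------
# Ranked trees (contemporaneous samples)
# ---------------------------------------------------------------------------

def enumerate_ranked(labels, allow_large: bool = False) -> set:
    """All ranked trees on a label set, by backward coalescence.

    Going back in time from ``n`` contemporaneous lineages, each of the
    ``n - 1`` coalescence steps merges one unordered pair; the step leaving
    ``j`` lineages creates the interior node of rank ``j`` (the root, created
    last, has rank 1).
    """
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels) or not labels:
        raise ValueError("labels must be non-empty and distinct")
    _check_cap(len(labels), RANKED_CAP, allow_large, "ranked trees")
    out: set = set()

    def rec(lineages: tuple) -> None:
        if len(lineages) == 1:
            out.add(lineages[0])
            return
        rank = len(lineages) - 1
        for i, j in combinations(range(len(lineages)), 2):
            a, b = sorted((lineages[i], lineages[j]))
            node = ("I", rank, a, b)
            rest = tuple(x for idx, x in enumerate(lineages) if idx not in (i, j))
            rec(rest + (node,))

    rec(tuple(("L", lab) for lab in labels))
    return out


# ---------------------------------------------------------------------------
# Fully ranked and FRS trees (serial samples)
# ---------------------------------------------------------------------------

def _default_groups(schedule) -> list[list[str]]:
    counts = tuple(schedule)
    return [[f"t{g + 1}_{i + 1}" for i in range(c)] for g, c in enumerate(counts)]


def _assign_levels(events: list) -> tuple[dict, dict]:
    """Map backward event tags to forward rank levels (root level = 1)."""
    merge_levels: dict[int, int] = {}
    sample_levels: dict[int, int] = {}
    level = 0
    for tag in reversed(events):
        level += 1
        kind, ident = tag
        if kind == "m":
            merge_levels[ident] = level
        else:
            sample_levels[ident] = level
    return merge_levels, sample_levels


def _apply_levels(node, merge_levels: dict, sample_levels: dict):
    kind = node[0]
    if kind == "L":
        return ("L", node[1], sample_levels[node[2]])
    if kind == "A":
        child = _apply_levels(node[3], merge_levels, sample_levels)
        return ("A", node[1], sample_levels[node[2]], child)
    left = _apply_levels(node[2], merge_levels, sample_levels)
    right = _apply_levels(node[3], merge_levels, sample_levels)
    if right < left:
        left, right = right, left
    return ("I", merge_levels[node[1]], left, right)


def enumerate_fully_ranked(schedule, labels=None, allow_large: bool = False) -> set:
    """All fully ranked trees whose pre-ranking realizes the schedule.

    ``schedule`` is ``(n_1, ..., n_m)``, oldest first; ``labels`` optionally
    gives the label groups (defaults to ``t<g>_<i>``).  The backward process
    interleaves pair-coalescences (one level each) with sampling events (one
    shared level for the group's leaves).
    """
    groups = [list(map(str, g)) for g in labels] if labels is not None else _default_groups(schedule)
    counts = tuple(len(g) for g in groups)
    if tuple(schedule) != counts:
        raise ValueError("label groups do not match the schedule")
    _check_cap(sum(counts), RANKED_CAP, allow_large, "fully ranked trees")
    out: set = set()
    m = len(groups)

    def rec(lineages: tuple, next_group: int, events: tuple, n_merges: int) -> None:
        if next_group < 0 and len(lineages) == 1:
            ml, sl = _assign_levels(list(events))
            out.add(_apply_levels(lineages[0], ml, sl))
            return
        if len(lineages) >= 2:
            rank_tag = n_merges + 1
            for i, j in combinations(range(len(lineages)), 2):
                node = ("I", rank_tag, lineages[i], lineages[j])
                rest = tuple(x for idx, x in enumerate(lineages) if idx not in (i, j))
                rec(rest + (node,), next_group, events + (("m", rank_tag),), n_merges + 1)
        if next_group >= 0:
            leaves = tuple(("L", lab, next_group) for lab in groups[next_group])
            rec(
                lineages + leaves,
                next_group - 1,
                events + (("s", next_group),),
                n_merges,
            )

    rec((), m - 1, (), 0)
    return out


def enumerate_frs(schedule, labels=None, allow_large: bool = False) -> set:
    """All FRS trees (fully ranked with sampled ancestors) for a schedule.

    As :func:`enumerate_fully_ranked`, except that at each sampling event any
    subset of that group's individuals may be placed *onto* distinct active
    lineages as direct ancestors (degree-2 nodes; a placement that ends up on
    top of the finished tree is the labelled degree-1 root) instead of
    starting new lineages.
    """
    groups = [list(map(str, g)) for g in labels] if labels is not None else _default_groups(schedule)
    counts = tuple(len(g) for g in groups)
    if tuple(schedule) != counts:
        raise ValueError("label groups do not match the schedule")
    _check_cap(sum(counts), FRS_CAP, allow_large, "FRS trees")
    out: set = set()
    m = len(groups)

    def sample_placements(lineages: tuple, group: list[str], gid: int):
        """Yield lineage tuples after the sampling event of ``group``."""
        n_lin = len(lineages)
        for j in range(0, min(n_lin, len(group)) + 1):
            for lin_subset in combinations(range(n_lin), j):
                for lab_subset in combinations(range(len(group)), j):
                    # labels are distinguishable: enumerate all bijections
                    def perms(pool):
                        if not pool:
                            yield ()
                            return
                        for idx, p in enumerate(pool):
                            for rest in perms(pool[:idx] + pool[idx + 1:]):
                                yield (p,) + rest

                    for assignment in perms(lab_subset):
                        new = list(lineages)
                        for pos, lab_i in zip(lin_subset, assignment):
                            new[pos] = ("A", group[lab_i], gid, new[pos])
                        fresh = [
                            ("L", group[i], gid)
                            for i in range(len(group))
                            if i not in lab_subset
                        ]
                        yield tuple(new) + tuple(fresh)

    def rec(lineages: tuple, next_group: int, events: tuple, n_merges: int) -> None:
        if next_group < 0 and len(lineages) == 1:
            ml, sl = _assign_levels(list(events))
            out.add(_apply_levels(lineages[0], ml, sl))
            return
        if len(lineages) >= 2:
            rank_tag = n_merges + 1
            for i, j in combinations(range(len(lineages)), 2):
                node = ("I", rank_tag, lineages[i], lineages[j])
                rest = tuple(x for idx, x in enumerate(lineages) if idx not in (i, j))
                rec(rest + (node,), next_group, events + (("m", rank_tag),), n_merges + 1)
        if next_group >= 0:
            for placed in sample_placements(lineages, groups[next_group], next_group):
                rec(placed, next_group - 1, events + (("s", next_group),), n_merges)

    rec((), m - 1, (), 0)
    return out


# ---------------------------------------------------------------------------
# Inspection helpers
# ---------------------------------------------------------------------------

def tree_leaf_ranks(tree) -> dict[str, int]:
    """Map each label of a (fully ranked or FRS) tree to its rank level."""
    out: dict[str, int] = {}

    def walk(node) -> None:
        kind = node[0]
        if kind == "L":
            out[node[1]] = node[2]
        elif kind == "A":
            out[node[1]] = node[2]
            walk(node[3])
        else:
            walk(node[2])
            walk(node[3])

    walk(tree)
    return out


def pre_ranking(tree) -> dict[str, int]:
    """Order-collapsed sampling-time indices ``ĥ: labels -> 1..m``.

    Two labels get the same index iff their sample nodes share a rank level,
    and indices increase with rank level.
    """
    ranks = tree_leaf_ranks(tree)
    ordering = {lev: i + 1 for i, lev in enumerate(sorted(set(ranks.values())))}
    return {lab: ordering[lev] for lab, lev in ranks.items()}


def clade_rank_map(tree) -> dict[frozenset, int]:
    """Map each interior node's descendant-leafset to its rank (binary trees)."""
    out: dict[frozenset, int] = {}

    def walk(node) -> frozenset:
        kind = node[0]
        if kind == "L":
            return frozenset((node[1],))
        if kind == "A":
            return walk(node[3]) | {node[1]}
        left = walk(node[2])
        right = walk(node[3])
        clade = left | right
        out[clade] = node[1]
        return clade

    walk(tree)
    return out


# ---------------------------------------------------------------------------
# Resolutions of constraint trees
# ---------------------------------------------------------------------------

def _constraint_clades(ctree: ConstraintTree) -> tuple[list[list[str]], dict[int, frozenset]]:
    """Leaf labels per subtree and the leafset of each interior node.

    Labels are ``x1..xn`` in subtree order, so all constraint trees on the
    same leaf count share one label set (and one cached enumeration table).
    """
    leaf_labels = []
    counter = 0
    for i in range(ctree.k):
        grp = []
        for _ in range(ctree.leaf_counts[i]):
            counter += 1
            grp.append(f"x{counter}")
        leaf_labels.append(grp)
    clades: dict[int, set] = {i: set(leaf_labels[i - 1]) for i in range(1, ctree.k + 1)}
    for child in range(ctree.k, 1, -1):  # children have higher numbers than parents
        clades[ctree.parents[child]] |= clades[child]
    return leaf_labels, {i: frozenset(s) for i, s in clades.items()}


@lru_cache(maxsize=4)
def _ranked_with_maps(labels: tuple[str, ...]) -> tuple:
    """Cached ``(tree, clade-rank map)`` pairs for all ranked trees on labels."""
    return tuple(
        (tree, clade_rank_map(tree))
        for tree in enumerate_ranked(labels, allow_large=True)
    )


@lru_cache(maxsize=64)
def _fully_ranked_with_maps(groups: tuple[tuple[str, ...], ...]) -> tuple:
    """Cached ``(tree, clade-rank map, leaf-level map)`` triples for all fully
    ranked trees on the given label groups."""
    schedule = tuple(len(g) for g in groups)
    return tuple(
        (tree, clade_rank_map(tree), tree_leaf_ranks(tree))
        for tree in enumerate_fully_ranked(schedule, labels=groups, allow_large=True)
    )


def embeds_in_ranked(ctree: ConstraintTree, clades: dict[int, frozenset], rank_map: dict[frozenset, int]) -> bool:
    """Embedding test: every constraint clade is a clade of the resolving
    tree and the constraint nodes' images appear in rank order."""
    prev = 0
    for i in range(1, ctree.k + 1):
        rank = rank_map.get(clades[i])
        if rank is None or rank <= prev:
            return False
        prev = rank
    return True


def enumerate_resolutions(ctree: ConstraintTree, allow_large: bool = False) -> set:
    """All ranked trees resolving a constraint tree, by enumerate-and-filter.

    Every ranked tree on the constraint tree's (arbitrarily labelled) leaves
    is generated and kept iff the constraint tree embeds into it: each
    constrained clade must appear as an exact clade, in the constrained rank
    order.
    """
    _check_cap(ctree.n, FRS_CAP, allow_large, "constraint-tree resolutions")
    leaf_labels, clades = _constraint_clades(ctree)
    all_labels = tuple(lab for grp in leaf_labels for lab in grp)
    return {
        tree
        for tree, rank_map in _ranked_with_maps(all_labels)
        if embeds_in_ranked(ctree, clades, rank_map)
    }


def enumerate_resolutions_constructive(ctree: ConstraintTree, allow_large: bool = False) -> set:
    """All ranked resolutions, built directly by constrained coalescence.

    Independent of :func:`enumerate_resolutions`: backward coalescence is
    pruned so that every intermediate lineage's leafset nests with every
    constraint clade, no unrealized clade is strictly swallowed, and clades
    are realized in reverse rank order.
    """
    _check_cap(ctree.n, FRS_CAP, allow_large, "constraint-tree resolutions")
    leaf_labels, clades = _constraint_clades(ctree)
    clade_list = [clades[i] for i in range(1, ctree.k + 1)]
    out: set = set()

    def rec(lineages: tuple, leafsets: tuple, next_expected: int) -> None:
        if len(lineages) == 1:
            out.add(lineages[0])
            return
        rank = len(lineages) - 1
        for i, j in combinations(range(len(lineages)), 2):
            merged = leafsets[i] | leafsets[j]
            expected = next_expected
            ok = True
            for idx, cl in enumerate(clade_list, start=1):
                inter = merged & cl
                if not inter:
                    continue
                if not (merged <= cl or cl <= merged):
                    ok = False  # straddles a constraint clade
                    break
                if merged == cl:
                    # realizing clade idx: must be the deepest unrealized one
                    if idx != expected:
                        ok = False
                        break
                    expected = idx - 1
                elif cl < merged and idx <= next_expected:
                    ok = False  # strictly swallows an unrealized clade
                    break
            if not ok:
                continue
            a, b = sorted((lineages[i], lineages[j]))
            node = ("I", rank, a, b)
            keep = [idx for idx in range(len(lineages)) if idx not in (i, j)]
            rec(
                tuple(lineages[x] for x in keep) + (node,),
                tuple(leafsets[x] for x in keep) + (merged,),
                expected,
            )

    leaves = tuple(("L", lab) for grp in leaf_labels for lab in grp)
    sets = tuple(frozenset((leaf[1],)) for leaf in leaves)
    rec(leaves, sets, ctree.k)
    return out


def enumerate_fr_resolutions(tree: FRConstraintTree, allow_large: bool = False) -> set:
    """All fully ranked trees resolving a fully ranked constraint tree.

    Enumerates every fully ranked tree on the constraint tree's sampling
    schedule and keeps those into which the constraint tree embeds: exact
    clades, with the joint (interior + leaf) level order and level-equality
    classes preserved.
    """
    _check_cap(tree.n, FRS_CAP, allow_large, "fully ranked resolutions")
    interior_levels = set(tree.ranks)
    # leaf labels per (level, subtree); schedule groups = leaf levels in order.
    # Group labels depend only on the schedule, so the enumeration table is
    # shared by all constraint trees with the same leaf-level profile.
    leaf_levels = [j for j in range(1, tree.l + 1) if j not in interior_levels]
    groups: list[tuple[str, ...]] = []
    label_level: dict[str, int] = {}
    clade_leaves: dict[int, set] = {i: set() for i in range(1, tree.k + 1)}
    for g, j in enumerate(leaf_levels):
        grp = []
        for i in range(1, tree.k + 1):
            for _ in range(tree.leaf_matrix[i - 1][j - 1]):
                lab = f"g{g + 1}x{len(grp) + 1}"
                grp.append(lab)
                label_level[lab] = j
                clade_leaves[i].add(lab)
        groups.append(tuple(grp))
    for ch in range(tree.k, 1, -1):
        clade_leaves[tree.parents[ch]] |= clade_leaves[ch]
    clades = {i: frozenset(s) for i, s in clade_leaves.items()}

    out = set()
    for cand, rank_map, leaf_map in _fully_ranked_with_maps(tuple(groups)):
        # images: constraint level -> set of image levels
        level_images: dict[int, set[int]] = {}
        ok = True
        for i in range(1, tree.k + 1):
            img = rank_map.get(clades[i])
            if img is None:
                ok = False
                break
            level_images.setdefault(tree.ranks[i - 1], set()).add(img)
        if ok:
            for lab, lev in label_level.items():
                level_images.setdefault(lev, set()).add(leaf_map[lab])
            # each constraint level maps to exactly one image level,
            # injectively and order-preservingly
            if any(len(s) != 1 for s in level_images.values()):
                ok = False
            else:
                pairs = sorted((lv, next(iter(s))) for lv, s in level_images.items())
                imgs = [im for _, im in pairs]
                ok = all(a < b for a, b in zip(imgs, imgs[1:]))
        if ok:
            out.add(cand)
    return out
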