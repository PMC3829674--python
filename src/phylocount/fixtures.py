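"""Deterministic random constraint-tree fixtures for testing.

Counting recursions are validated against exhaustive enumeration on many
small instances; this module generates those instances.  Generation is fully
deterministic given the seed, spans the edge cases (single-node stars, fully
binary trees, mixed multifurcations, interleaved leaf levels) and respects
the size caps, so oracle enumeration stays cheap.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .constraints import ConstraintTree
from .fr_constraints import FRConstraintTree

__all__ = ["FixtureSpec", "generate_fixtures"]


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: ``kind`` is ``"ranked"`` or ``"fully-ranked"``."""

    seed: int
    count: int
    kind: str = "ranked"
    max_leaves: int = 7
    max_interior: int = 4
    max_levels: int = 5


def _random_ranked(rng: random.Random, max_n: int, max_k: int) -> ConstraintTree:
    while True:
        k = rng.randint(1, max_k)
        parents = {i: rng.randint(1, i - 1) for i in range(2, k + 1)}
        alpha = [0] * k
        for p in parents.values():
            alpha[p - 1] += 1
        counts = [max(0, 2 - alpha[i]) + rng.choice((0, 0, 1, 1, 2)) for i in range(k)]
        if 2 <= sum(counts) <= max_n:
            try:
                return ConstraintTree(tuple(counts), parents)
            except ValueError:
                continue


def _binary_caterpillar(k: int) -> ConstraintTree:
    # fully binary ranked tree: node i has node i+1 and one leaf as children
    counts = [1] * (k - 1) + [2] if k > 1 else [2]
    parents = {i: i - 1 for i in range(2, k + 1)}
    return ConstraintTree(tuple(counts), parents)


def _random_fully_ranked(
    rng: random.Random, max_n: int, max_k: int, max_l: int
) -> FRConstraintTree:
    while True:
        k = rng.randint(1, min(max_k, max_l - 1))
        parents = {i: rng.randint(1, i - 1) for i in range(2, k + 1)}
        l = k + rng.randint(1, max_l - k)
        pool = list(range(2, l))
        if len(pool) < k - 1:
            continue
        ranks = tuple([1] + sorted(rng.sample(pool, k - 1)))
        leaf_cols = [j for j in range(1, l + 1) if j not in set(ranks)]
        rows = [[0] * l for _ in range(k)]
        alpha = [0] * k
        for p in parents.values():
            alpha[p - 1] += 1
        n_leaves = 0
        ok = True
        for i in range(k):
            for _ in range(max(0, 2 - alpha[i])):
                avail = [j for j in leaf_cols if j > ranks[i]]
                if not avail:
                    ok = False
                    break
                rows[i][rng.choice(avail) - 1] += 1
                n_leaves += 1
            if not ok:
                break
        if not ok:
            continue
        for j in leaf_cols:  # every level must be occupied
            if not any(rows[i][j - 1] for i in range(k)):
                hosts = [i for i in range(k) if ranks[i] < j]
                if not hosts:
                    ok = False
                    break
                rows[rng.choice(hosts)][j - 1] += 1
                n_leaves += 1
        if not ok or n_leaves > max_n:
            continue
        while n_leaves < max_n and rng.random() < 0.4:
            i = rng.randrange(k)
            avail = [j for j in leaf_cols if j > ranks[i]]
            if avail:
                rows[i][rng.choice(avail) - 1] += 1
                n_leaves += 1
        try:
            return FRConstraintTree(ranks, tuple(tuple(r) for r in rows), parents)
        except ValueError:
            continue


def generate_fixtures(spec: FixtureSpec) -> list:
    """Generate ``spec.count`` valid constraint trees, deterministically.

    The list starts with deterministic edge cases (a two-leaf tree, a star on
    ``max_leaves`` leaves, a fully binary tree) and continues with random
    instances.
    """
    rng = random.Random(spec.seed)
    out: list = []
    if spec.kind == "ranked":
        edge = [
            ConstraintTree((2,)),
            ConstraintTree((spec.max_leaves,)),
            _binary_caterpillar(min(spec.max_interior, spec.max_leaves - 1)),
        ]
        out.extend(edge[: spec.count])
        while len(out) < spec.count:
            out.append(_random_ranked(rng, spec.max_leaves, spec.max_interior))
    elif spec.kind == "fully-ranked":
        edge = [
            FRConstraintTree((1,), ((0, 2),), {}),
            FRConstraintTree((1,), ((0, 1, 1),), {}),
            FRConstraintTree((1,), ((0,) + (1,) * min(spec.max_levels - 1, spec.max_leaves),), {}),
        ]
        out.extend(edge[: spec.count])
        while len(out) < spec.count:
            out.append(
                _random_fully_ranked(rng, spec.max_leaves, spec.max_interior, spec.max_levels)
            )
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return out
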