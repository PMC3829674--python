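"""The enumeration oracle: explicit tree construction and embedding filters."""

import pytest

from phylocount.constraints import ConstraintTree
from phylocount.exact import count_ranked
from phylocount.fr_constraints import FRConstraintTree
from phylocount.oracle import (
    enumerate_fr_resolutions,
    enumerate_frs,
    enumerate_fully_ranked,
    enumerate_ranked,
    enumerate_resolutions,
    enumerate_resolutions_constructive,
    pre_ranking,
    tree_leaf_ranks,
)


def assert_valid_binary_ranked(tree, n_leaves):
    """Structural invariants of an explicit (fully) ranked tree."""
    seen_ranks = []
    leaves = []

    def walk(node, parent_rank):
        if node[0] == "L":
            leaves.append(node[1])
            if len(node) > 2:
                assert node[2] > parent_rank  # leaves rank below ancestors
            return
        assert node[0] == "I"
        rank = node[1]
        assert rank > parent_rank  # ancestor-monotone ranking
        seen_ranks.append(rank)
        assert len(node) == 4  # binary
        walk(node[2], rank)
        walk(node[3], rank)

    walk(tree, 0)
    assert len(leaves) == len(set(leaves)) == n_leaves
    assert len(seen_ranks) == n_leaves - 1
    assert len(set(seen_ranks)) == len(seen_ranks)  # interior ranks distinct


class TestRanked:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_cardinality_matches_closed_form(self, n):
        labels = [chr(ord("A") + i) for i in range(n)]
        assert len(enumerate_ranked(labels)) == count_ranked(n)

    def test_emitted_trees_are_valid(self):
        for tree in enumerate_ranked("ABCD"):
            assert_valid_binary_ranked(tree, 4)

    def test_cap_refusal(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_ranked([f"x{i}" for i in range(9)])


class TestFullyRanked:
    @pytest.mark.parametrize(
        "schedule, expected", [((1, 1), 1), ((2, 1), 3), ((1, 2), 4)]
    )
    def test_small_schedules(self, schedule, expected):
        assert len(enumerate_fully_ranked(schedule)) == expected

    def test_leaf_levels_respect_schedule(self):
        for tree in enumerate_fully_ranked((2, 2)):
            pr = pre_ranking(tree)
            assert sorted(pr.values()) == [1, 1, 2, 2]
            assert pr["t1_1"] == pr["t1_2"] == 1
            assert pr["t2_1"] == pr["t2_2"] == 2


class TestFRS:
    @pytest.mark.parametrize("schedule, expected", [((1, 1), 2), ((2, 1), 5)])
    def test_small_schedules(self, schedule, expected):
        assert len(enumerate_frs(schedule)) == expected

    def test_single_time_point_has_no_ancestors(self):
        """With one sampling time the FRS and plain ranked spaces coincide."""
        frs = enumerate_frs((4,))
        assert len(frs) == count_ranked(4)
        assert all("A" not in {nd[0] for nd in _nodes(t)} for t in frs)


def _nodes(tree):
    stack = [tree]
    while stack:
        nd = stack.pop()
        yield nd
        if nd[0] == "I":
            stack.extend([nd[2], nd[3]])
        elif nd[0] == "A":
            stack.append(nd[3])


class TestPreRanking:
    def test_grouped_leaves(self):
        tree = sorted(enumerate_fully_ranked((3, 2)))[0]
        pr = pre_ranking(tree)
        assert {pr["t1_1"], pr["t1_2"], pr["t1_3"]} == {1}
        assert {pr["t2_1"], pr["t2_2"]} == {2}

    def test_contemporaneous_tree_collapses_to_one(self):
        tree = sorted(enumerate_fully_ranked((3,)))[0]
        assert set(pre_ranking(tree).values()) == {1}

    def test_order_isomorphic_to_levels(self):
        tree = sorted(enumerate_fully_ranked((1, 1, 1)))[0]
        levels = tree_leaf_ranks(tree)
        pr = pre_ranking(tree)
        labs = sorted(levels, key=levels.get)
        assert [pr[x] for x in labs] == [1, 2, 3]


class TestResolutions:
    @pytest.mark.parametrize(
        "tree, expected",
        [
            (ConstraintTree((2,)), 1),
            (ConstraintTree((4,)), 18),
            (ConstraintTree((3, 3), {2: 1}), 135),
        ],
    )
    def test_filter_route(self, tree, expected):
        assert len(enumerate_resolutions(tree)) == expected

    def test_two_oracle_strategies_agree(self, ranked_fixture_trees):
        """Enumerate-all-then-filter and constrained coalescence must produce
        the same tree sets."""
        for tree in ranked_fixture_trees:
            assert enumerate_resolutions(tree) == enumerate_resolutions_constructive(
                tree
            ), tree


class TestFRResolutions:
    def test_two_leaf_bases(self):
        for mat in (((0, 2),), ((0, 1, 1),)):
            tree = FRConstraintTree((1,), mat, {})
            assert len(enumerate_fr_resolutions(tree)) == 1

    def test_star_over_schedule(self):
        star = FRConstraintTree((1,), ((0, 2, 1),), {})
        assert len(enumerate_fr_resolutions(star)) == 3

    def test_single_level_matches_ranked_resolutions(self, ranked_fixture_trees):
        for ctree in ranked_fixture_trees[:12]:
            k = ctree.k
            rows = [[0] * (k + 1) for _ in range(k)]
            for i in range(k):
                rows[i][k] = ctree.leaf_counts[i]
            fr = FRConstraintTree(
                tuple(range(1, k + 1)), tuple(tuple(r) for r in rows), ctree.parents
            )
            assert len(enumerate_fr_resolutions(fr)) == len(
                enumerate_resolutions(ctree)
            ), ctree
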