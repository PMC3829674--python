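"""Fully ranked constraint trees: moves, bounds and resolution counts."""

import pytest

from phylocount.constraints import ConstraintTree, count_resolutions
from phylocount.fr_constraints import (
    FRConstraintTree,
    candidate_set,
    count_fr_resolutions,
    count_fr_resolutions_naive,
    merge_last_node,
    reduce_leaf,
)
from phylocount.serial import count_fully_ranked

STAR_21 = FRConstraintTree((1,), ((0, 2, 1),), {})
BASE_SAME = FRConstraintTree((1,), ((0, 2),), {})
BASE_SPLIT = FRConstraintTree((1,), ((0, 1, 1),), {})


class TestValidation:
    def test_examples_accepted(self):
        assert BASE_SAME.n == 2
        assert STAR_21.l == 3 and STAR_21.n == 3

    def test_root_rank_must_be_one(self):
        with pytest.raises(ValueError, match="rank 1"):
            FRConstraintTree((2,), ((0, 0, 2),), {})

    def test_leaf_above_parent_rejected(self):
        # leaf of the rank-2 node placed at level 2 itself
        with pytest.raises(ValueError):
            FRConstraintTree((1, 2), ((0, 0, 1), (0, 2, 0)), {2: 1})

    def test_too_few_children_rejected(self):
        with pytest.raises(ValueError, match="child"):
            FRConstraintTree((1,), ((0, 1),), {})

    def test_empty_level_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            FRConstraintTree((1,), ((0, 0, 2),), {})


class TestCandidateSet:
    def test_star_levels(self):
        assert candidate_set(STAR_21, 2) == {1}
        assert candidate_set(STAR_21, 3) == set()

    def test_two_leaf_trees_have_no_candidates(self):
        for tree in (BASE_SAME, BASE_SPLIT):
            for p in range(2, tree.l + 1):
                assert candidate_set(tree, p) == set()

    def test_out_of_range_level(self):
        with pytest.raises(ValueError):
            candidate_set(STAR_21, 1)


class TestMoves:
    def test_reduce_drops_one_leaf(self):
        reduced = reduce_leaf(STAR_21, 1, 2)
        assert reduced.n == STAR_21.n - 1
        assert reduced == BASE_SAME

    def test_reduce_requires_candidate(self):
        with pytest.raises(ValueError):
            reduce_leaf(STAR_21, 1, 3)

    def test_merge_requires_cherry(self):
        tree = FRConstraintTree((1, 2), ((0, 0, 0, 1), (0, 0, 3, 0)), {2: 1})
        with pytest.raises(ValueError, match="exactly 2"):
            merge_last_node(tree)

    def test_merge_absorbs_cherry_node(self):
        tree = FRConstraintTree((1, 2), ((0, 0, 0, 1), (0, 0, 2, 0)), {2: 1})
        merged = merge_last_node(tree)
        assert merged.k == 1
        assert merged.n == tree.n - 1  # two leaves out, one new leaf in

    def test_merge_refuses_root(self):
        with pytest.raises(ValueError, match="k >= 2"):
            merge_last_node(BASE_SAME)


class TestCounts:
    @pytest.mark.parametrize("tree, expected", [(BASE_SAME, 1), (BASE_SPLIT, 1), (STAR_21, 3)])
    def test_base_and_star_values(self, tree, expected):
        assert count_fr_resolutions_naive(tree) == expected
        assert count_fr_resolutions(tree) == expected

    def test_dynamic_equals_reference_on_fixtures(self, fr_fixture_trees):
        for tree in fr_fixture_trees:
            assert count_fr_resolutions(tree) == count_fr_resolutions_naive(tree), tree

    @pytest.mark.parametrize(
        "schedule",
        [(2,), (1, 1), (2, 1), (1, 2), (3, 2), (2, 2, 2), (1, 3, 2), (4, 1, 3)],
    )
    def test_star_reduces_to_serial_count(self, schedule):
        """A root-only constraint tree over a schedule constrains nothing:
        its resolutions are all fully ranked trees on that schedule."""
        row = (0,) + tuple(schedule)
        star = FRConstraintTree((1,), (row,), {})
        assert count_fr_resolutions(star) == count_fully_ranked(schedule)

    def test_single_leaf_level_reduces_to_ranked_case(self, ranked_fixture_trees):
        """All leaves at one time point: the count equals the plain ranked
        constraint-tree resolution count."""
        for ctree in ranked_fixture_trees:
            k = ctree.k
            rows = [[0] * (k + 1) for _ in range(k)]
            for i in range(k):
                rows[i][k] = ctree.leaf_counts[i]
            fr = FRConstraintTree(
                tuple(range(1, k + 1)), tuple(tuple(r) for r in rows), ctree.parents
            )
            assert count_fr_resolutions(fr) == count_resolutions(ctree), ctree

    def test_count_bounded_by_schedule_space(self, fr_fixture_trees):
        """1 <= Fr(tree) <= F(schedule of its leaf levels)."""
        for tree in fr_fixture_trees:
            interior = set(tree.ranks)
            schedule = tuple(
                sum(tree.leaf_matrix[i][j - 1] for i in range(tree.k))
                for j in range(1, tree.l + 1)
                if j not in interior
            )
            value = count_fr_resolutions(tree)
            assert 1 <= value <= count_fully_ranked(schedule), tree
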