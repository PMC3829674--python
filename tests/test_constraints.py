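"""Ranked constraint trees: validation, bounds matrices, resolution counts."""

import pytest

from phylocount.constraints import (
    ConstraintTree,
    bounds_matrices,
    count_resolutions,
    count_resolutions_naive,
)
from phylocount.exact import count_ranked

FIG_TREE = ConstraintTree((0, 2, 3, 2), {2: 1, 3: 1, 4: 2})


class TestValidation:
    def test_worked_example_tree(self):
        assert FIG_TREE.n == 7
        assert FIG_TREE.interior_children == (2, 1, 0, 0)

    def test_two_leaf_tree(self):
        assert ConstraintTree((2,)).k == 1

    def test_single_child_root_rejected(self):
        with pytest.raises(ValueError, match="multifurcated"):
            ConstraintTree((1,))

    def test_rank_order_violation_rejected(self):
        with pytest.raises(ValueError, match="rank order"):
            ConstraintTree((0, 2), {2: 3})

    def test_parent_map_must_cover_all_nonroot_nodes(self):
        with pytest.raises(ValueError):
            ConstraintTree((2, 2), {})


class TestBoundsMatrices:
    def test_worked_example_entries(self):
        b = bounds_matrices(FIG_TREE)
        assert b.entry("m", 2, 2) == 2
        assert b.entry("M", 2, 2) == 3
        assert b.entry("m", 1, 2) == b.entry("M", 1, 2) == 1

    def test_star_bounds(self):
        b = bounds_matrices(ConstraintTree((6,)))
        assert b.entry("m", 1, 1) == 2
        assert b.entry("M", 1, 1) == 6

    def test_lower_never_exceeds_upper(self):
        b = bounds_matrices(FIG_TREE)
        for i in range(1, 5):
            for j in range(i, 5):
                assert b.entry("m", i, j) <= b.entry("M", i, j)


class TestResolutionCounts:
    @pytest.mark.parametrize(
        "tree, expected",
        [
            (ConstraintTree((2,)), 1),
            (ConstraintTree((4,)), 18),
            (ConstraintTree((1, 2), {2: 1}), 1),
            (ConstraintTree((3, 3), {2: 1}), 135),
            (FIG_TREE, 54),
        ],
    )
    def test_reference_values(self, tree, expected):
        assert count_resolutions_naive(tree) == expected
        assert count_resolutions(tree) == expected

    @pytest.mark.parametrize("n", [2, 3, 10, 30])
    def test_star_reduces_to_closed_form(self, n):
        """A star imposes no constraint beyond the root: Rr((n,)) = R(n)."""
        assert count_resolutions(ConstraintTree((n,))) == count_ranked(n)

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_fully_binary_tree_has_unique_resolution(self, k):
        counts = tuple([1] * (k - 1) + [2]) if k > 1 else (2,)
        parents = {i: i - 1 for i in range(2, k + 1)}
        assert count_resolutions(ConstraintTree(counts, parents)) == 1

    def test_dynamic_equals_reference_on_fixtures(self, ranked_fixture_trees):
        for tree in ranked_fixture_trees:
            assert count_resolutions(tree) == count_resolutions_naive(tree), tree

    def test_count_bounded_by_tree_space(self, ranked_fixture_trees):
        for tree in ranked_fixture_trees:
            assert 1 <= count_resolutions(tree) <= count_ranked(tree.n)


def refine_one_multifurcation(tree: ConstraintTree) -> ConstraintTree | None:
    """Replace two leaves of a >2-child node by a new deepest cherry node."""
    alpha = tree.interior_children
    for i in range(tree.k):
        if tree.leaf_counts[i] >= 2 and tree.leaf_counts[i] + alpha[i] > 2:
            counts = list(tree.leaf_counts)
            counts[i] -= 2
            counts.append(2)
            parents = dict(tree.parents)
            parents[tree.k + 1] = i + 1
            return ConstraintTree(tuple(counts), parents)
    return None


def test_refinement_never_increases_count(ranked_fixture_trees):
    """Adding a compatible cherry constraint can only shrink the space."""
    refined_any = False
    for tree in ranked_fixture_trees:
        refined = refine_one_multifurcation(tree)
        if refined is not None:
            refined_any = True
            assert count_resolutions(refined) <= count_resolutions(tree)
    assert refined_any
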