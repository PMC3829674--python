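"""Serial-sample counts F and S: recursions, dynamic programs, identities."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylocount.exact import count_ranked
from phylocount.serial import (
    SampleSchedule,
    count_frs,
    count_frs_naive,
    count_fully_ranked,
    count_fully_ranked_naive,
)

schedules_strategy = st.lists(
    st.integers(min_value=1, max_value=4), min_size=1, max_size=4
).map(tuple)


class TestSampleSchedule:
    def test_suffix_sums(self):
        s = SampleSchedule((2, 3, 1))
        assert s.m == 3 and s.n == 6
        assert s.suffix_sums == (6, 4, 1, 0)

    @pytest.mark.parametrize("bad", [(), (0,), (2, -1)])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            SampleSchedule(bad)


class TestFullyRanked:
    @pytest.mark.parametrize(
        "schedule, expected",
        [((4,), 18), ((1, 1), 1), ((2, 1), 3), ((1, 2), 4)],
    )
    def test_reference_values(self, schedule, expected):
        assert count_fully_ranked_naive(schedule) == expected

    @pytest.mark.parametrize(
        "schedule",
        [(2, 1), (1, 1, 1), (3, 4), (4, 1, 2), (2, 2, 2, 2), (50, 50, 50)],
    )
    def test_dynamic_equals_reference(self, schedule):
        assert count_fully_ranked(schedule) == count_fully_ranked_naive(schedule)

    def test_not_permutation_invariant(self):
        assert count_fully_ranked((2, 1)) != count_fully_ranked((1, 2))


class TestSampledAncestors:
    @pytest.mark.parametrize(
        "schedule, expected",
        [((3,), 3), ((1, 1), 2), ((2, 1), 5), ((2, 2), 37)],
    )
    def test_reference_values(self, schedule, expected):
        # (2,2): 21 ancestor-free trees, 14 with one sampled ancestor, and 2
        # with both older samples ancestral (one per label-to-lineage matching)
        assert count_frs_naive(schedule) == expected

    @pytest.mark.parametrize(
        "schedule", [(2, 1), (3, 2), (1, 1, 1), (4, 2, 3), (10, 10, 10)]
    )
    def test_dynamic_equals_reference(self, schedule):
        assert count_frs(schedule) == count_frs_naive(schedule)


@pytest.mark.parametrize("n", [1, 2, 5, 30, 200])
def test_single_time_point_identities(n):
    """With one sampling time there is nothing to interleave and no possible
    ancestor: F(n) = S(n) = R(n)."""
    r = count_ranked(n)
    assert count_fully_ranked((n,)) == r
    assert count_frs((n,)) == r


@given(schedules_strategy)
def test_frs_space_contains_fully_ranked_space(schedule):
    """Fully ranked trees are the zero-ancestor FRS trees, so S >= F."""
    assert count_frs(schedule) >= count_fully_ranked(schedule)


@given(schedules_strategy)
def test_dynamic_programs_match_reference(schedule):
    assert count_fully_ranked(schedule) == count_fully_ranked_naive(schedule)
    assert count_frs(schedule) == count_frs_naive(schedule)


def test_empty_schedule_rejected():
    with pytest.raises(ValueError):
        count_fully_ranked(())
    with pytest.raises(ValueError):
        count_frs(())
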