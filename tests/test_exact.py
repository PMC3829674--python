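"""The closed form R(n) and its exact ratio/binomial companions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylocount.exact import binomial, count_ranked, ranked_ratio, ranked_table


def ranked_by_products(n: int) -> int:
    """Independent route to R(n): one pair choice per coalescence step."""
    out = 1
    for j in range(2, n + 1):
        out *= j * (j - 1) // 2
    return out


@pytest.mark.parametrize(
    "n, expected",
    [(0, 1), (1, 1), (2, 1), (3, 3), (4, 18), (7, 56700)],
)
def test_count_ranked_small_values(n, expected):
    assert count_ranked(n) == expected


def test_count_ranked_matches_product_formula():
    for n in range(0, 60):
        assert count_ranked(n) == ranked_by_products(n)


def test_count_ranked_rejects_negative():
    with pytest.raises(ValueError):
        count_ranked(-1)


@pytest.mark.parametrize("a, b, expected", [(5, 5, 1), (3, 1, 3), (4, 2, 18), (2, 0, 1)])
def test_ranked_ratio_examples(a, b, expected):
    assert ranked_ratio(a, b) == expected


@given(st.integers(min_value=1, max_value=50), st.integers(min_value=1, max_value=50))
def test_ranked_ratio_consistency(a, b):
    """R(a)/R(b) times R(b) recovers R(a), and equals the pair-choice product."""
    a, b = max(a, b), min(a, b)
    ratio = ranked_ratio(a, b)
    assert ratio * count_ranked(b) == count_ranked(a)
    prod = 1
    for j in range(b + 1, a + 1):
        prod *= binomial(j, 2)
    assert ratio == prod


def test_ranked_ratio_rejects_bad_order():
    with pytest.raises(ValueError):
        ranked_ratio(2, 5)


@pytest.mark.parametrize(
    "n, k, expected",
    [(4, 2, 6), (7, 0, 1), (0, 0, 1), (3, 5, 0), (3, -1, 0)],
)
def test_binomial_conventions(n, k, expected):
    assert binomial(n, k) == expected


def test_ranked_table_agrees_with_closed_form():
    table = ranked_table(40)
    assert table == [count_ranked(j) for j in range(41)]
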