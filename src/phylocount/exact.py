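"""Exact integer primitives for ranked-tree counting.

Everything in this package is arbitrary-precision integer arithmetic; no count
is ever represented in floating point.  The central quantity is

    R(n) = n! (n-1)! / 2^(n-1),

the number of ranked trees on ``n`` contemporaneous labelled leaves — rooted
binary trees whose interior nodes carry a total time-order consistent with
ancestry.  Every other counting routine in the package reduces to products and
ratios of ``R``.
"""

from __future__ import annotations

import math

__all__ = ["count_ranked", "ranked_ratio", "binomial", "ranked_table"]


def count_ranked(n: int) -> int:
    """Number ``R(n)`` of ranked trees on ``n`` labelled leaves.

    A ranked tree is a rooted binary phylogenetic tree together with a linear
    order on its interior nodes that is consistent with ancestry; equivalently,
    a coalescent history of ``n`` contemporaneous lineages.

    ``R(n) = n!(n-1)!/2^(n-1)``.  By convention ``R(0) = R(1) = 1``: the
    recursions built on top of this function divide by ``R(α)`` at ``α = 0``
    and evaluate ``R(1)``, and 1 is the unique convention consistent with them.

    Raises
    ------
    ValueError
        If ``n`` is negative.
    """
    if n < 0:
        raise ValueError(f"count_ranked requires n >= 0, got {n}")
    if n <= 1:
        return 1
    num = math.factorial(n) * math.factorial(n - 1)
    # 2^(n-1) always divides n!(n-1)!; use an exact shift.
    return num >> (n - 1)


def ranked_ratio(a: int, b: int) -> int:
    """Exact integer ratio ``R(a)/R(b)`` for ``a >= b``.

    This is the number of ranked coalescent histories taking ``a`` lineages
    down to ``b`` lineages: each of the ``a - b`` coalescence steps merges one
    unordered pair, so the ratio equals ``prod_{j=b+1}^{a} C(j, 2)``.  It is
    computed as that product of pair choices, never by dividing factorials.

    Raises
    ------
    ValueError
        If ``a < b`` or ``b < 0``.
    """
    if b < 0:
        raise ValueError(f"ranked_ratio requires b >= 0, got b={b}")
    if a < b:
        raise ValueError(f"ranked_ratio requires a >= b, got a={a} < b={b}")
    out = 1
    for j in range(max(b, 1) + 1, a + 1):
        out *= j * (j - 1) // 2
    return out


def binomial(n: int, k: int) -> int:
    """Binomial coefficient ``C(n, k)`` with the out-of-range convention.

    Returns 0 when ``k < 0`` or ``k > n``, which lets summations over lineage
    choices run over formally too-wide index ranges without special-casing.
    """
    if k < 0 or k > n:
        return 0
    return math.comb(n, k)


def ranked_table(n: int) -> list[int]:
    """Table ``[R(0), R(1), ..., R(n)]`` built by the pair-choice recurrence.

    The dynamic counting algorithms consume many ``R`` values; building the
    table incrementally (``R(j) = R(j-1) * C(j,2)``) costs one big-integer
    multiply per entry.
    """
    if n < 0:
        raise ValueError(f"ranked_table requires n >= 0, got {n}")
    table = [1] * (n + 1)
    for j in range(2, n + 1):
        table[j] = table[j - 1] * (j * (j - 1) // 2)
    return table
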