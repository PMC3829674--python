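"""Counting tree spaces for serially sampled (heterochronous) data.

A *sample schedule* ``(n_1, ..., n_m)`` records how many individuals were
sampled at each of ``m`` time points, oldest first.  Two tree spaces are
counted here:

* ``F(n_1, ..., n_m)`` — fully ranked trees: binary trees in which interior
  nodes are totally ordered and leaves are ranked by sampling time (leaves may
  share a rank, interior nodes may not).

* ``S(n_1, ..., n_m)`` — fully ranked trees with sampled ancestors (FRS
  trees): as above, but a sampled individual may also sit *on* a lineage as a
  degree-2 node (or be a degree-1 root), i.e. be a direct ancestor of later
  samples.

For each space there is a reference recursion (``*_naive``, a direct memoized
transcription of the defining recurrence) and a dynamic program
(``count_fully_ranked`` in O(m·n) big-integer steps, ``count_frs`` in
O(m·n²)).  Both routes return identical exact integers; the fast routes raise
if an internal consistency check fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from .exact import binomial, count_ranked, ranked_table

__all__ = [
    "SampleSchedule",
    "count_fully_ranked_naive",
    "count_fully_ranked",
    "count_frs_naive",
    "count_frs",
]


@dataclass(frozen=True)
class SampleSchedule:
    """An ordered sequence of per-time-point sample counts, oldest first.

    ``counts[0]`` is the number of individuals sampled at the earliest time
    point.  ``suffix_sums[j]`` is ``N_{j+1} = n_{j+1} + ... + n_m`` in 1-based
    notation, i.e. the number of individuals sampled at time point ``j+1``
    (0-based ``j``) or later.
    """

    counts: tuple[int, ...]
    suffix_sums: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) == 0:
            raise ValueError("a sample schedule needs at least one time point")
        if any(c < 1 for c in counts):
            raise ValueError(f"all sample counts must be >= 1, got {counts}")
        object.__setattr__(self, "counts", counts)
        suffix = [0] * (len(counts) + 1)
        for j in range(len(counts) - 1, -1, -1):
            suffix[j] = suffix[j + 1] + counts[j]
        object.__setattr__(self, "suffix_sums", tuple(suffix))

    @property
    def m(self) -> int:
        """Number of sampling time points."""
        return len(self.counts)

    @property
    def n(self) -> int:
        """Total number of sampled individuals."""
        return self.suffix_sums[0]


def _as_schedule(schedule: SampleSchedule | tuple[int, ...] | list[int]) -> SampleSchedule:
    if isinstance(schedule, SampleSchedule):
        return schedule
    return SampleSchedule(tuple(schedule))


# ---------------------------------------------------------------------------
# Reference recursions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _f_naive(counts: tuple[int, ...]) -> int:
    # F(n_1, ..., n_m) = sum_i R(n_m)/R(i) * F(n_1, ..., n_{m-1} + i); F(n) = R(n).
    # Backwards in time the n_m newest lineages coalesce down to i lineages
    # (R(n_m)/R(i) ranked histories), which are then treated as i extra
    # samples at time point m-1.
    if len(counts) == 1:
        return count_ranked(counts[0])
    *head, last = counts
    total = 0
    for i in range(1, last + 1):
        ratio = 1
        for j in range(i + 1, last + 1):
            ratio *= j * (j - 1) // 2
        rest = tuple(head[:-1]) + (head[-1] + i,)
        total += ratio * _f_naive(rest)
    return total


def count_fully_ranked_naive(schedule: SampleSchedule | tuple[int, ...] | list[int]) -> int:
    """Count fully ranked trees for a schedule by the defining recursion."""
    return _f_naive(_as_schedule(schedule).counts)


@lru_cache(maxsize=None)
def _s_naive(counts: tuple[int, ...]) -> int:
    # S(n_1,...,n_m) = sum_{i=1}^{n_m} sum_{j=0}^{min(i, n_{m-1})}
    #     C(i,j) C(n_{m-1},j) j! R(n_m)/R(i) S(n_1,...,n_{m-1}+i-j);  S(n) = R(n).
    # i ancestral lineages survive back to time m-1, j of which carry
    # individuals sampled at time m-1 (sampled ancestors): choose the j
    # lineages, the j individuals, and one of the j! assignments between them.
    if len(counts) == 1:
        return count_ranked(counts[0])
    *head, last = counts
    prev = head[-1]
    total = 0
    for i in range(1, last + 1):
        ratio = 1
        for j in range(i + 1, last + 1):
            ratio *= j * (j - 1) // 2
        for j in range(0, min(i, prev) + 1):
            rest = tuple(head[:-1]) + (prev + i - j,)
            total += (
                binomial(i, j) * binomial(prev, j) * math.factorial(j) * ratio * _s_naive(rest)
            )
    return total


def count_frs_naive(schedule: SampleSchedule | tuple[int, ...] | list[int]) -> int:
    """Count FRS (sampled-ancestor) trees for a schedule by the defining recursion."""
    return _s_naive(_as_schedule(schedule).counts)


# ---------------------------------------------------------------------------
# Dynamic algorithms
# ---------------------------------------------------------------------------

def count_fully_ranked(schedule: SampleSchedule | tuple[int, ...] | list[int]) -> int:
    """Count fully ranked trees in O(m·n) big-integer operations.

    Sweeps the schedule oldest-to-newest keeping, for time point ``j``, the
    value ``F(n_1, ..., n_j + α)`` for every admissible surplus ``α`` of
    lineages crossing back past time point ``j``.  The inner prefix sum
    ``P(T) = Σ_{i<=T} F(n_1,...,n_{j-1}+i)/R(i)`` is carried in the
    denominator-cleared form ``P(T)·R(T)``, which stays integral:
    ``P(T+1)·R(T+1) = P(T)·R(T)·C(T+1,2) + F(n_1,...,n_{j-1}+T+1)``, and
    ``F(n_1, ..., n_j + α)`` is exactly the cleared prefix at ``T = n_j + α``.
    """
    sched = _as_schedule(schedule)
    counts = sched.counts
    if sched.m == 1:
        return count_ranked(counts[0])
    # fvals[a] = F(n_1, ..., n_j + a) for the current j.
    limit = sched.suffix_sums[1]  # largest inflated first group: n_1 + N_2
    r = ranked_table(counts[0] + limit)
    fvals = [r[counts[0] + a] for a in range(limit + 1)]
    for j in range(1, sched.m):
        nj = counts[j]
        limit = sched.suffix_sums[j + 1]  # α ranges over 0..N_{j+2}
        new: list[int] = [0] * (limit + 1)
        cleared = 0  # P(T)·R(T), starting at T = 0
        top = nj + limit
        for t in range(1, top + 1):
            cleared = cleared * (t * (t - 1) // 2) + fvals[t]
            a = t - nj
            if a >= 0:
                new[a] = cleared
        fvals = new
    result = fvals[0]
    if result < 0:
        raise RuntimeError("internal error: negative tree count")
    return result


def _frs_initial_coeffs(a: int, b: int) -> list[int]:
    """Coefficient table ``A(i, a, b)`` for ``0 <= i <= b``.

    ``A(i, a, b) = Σ_x R(b)/R(i+x) · C(i+x, x) · C(a, x) · x!`` over
    ``0 <= x <= min(a, b-i)`` is the number of ways ``b`` lineages coalesce
    back to ``i + x`` lineages of which ``x`` are matched, injectively, onto
    older sampled individuals; the degenerate ``i + x = 0`` term is excluded
    (at least one ancestral lineage must survive).  Built via the summand
    recursions: with ``B(i, a, b, x)`` the ``x`` summand and ``β = b - i``,

        B(b, a, b, 0) = 1,
        B(b-β-1, a, b, x)   = (b-β-1+x)(b-β)/2 · B(b-β, a, b, x),
        B(b-β-1, a, b, β+1) = (b-β)(a-β)/(β+1) · B(b-β, a, b, β).

    All ``B`` are integers (``R(b)/R(i+x)`` divides exactly); the divisions
    are checked.
    """
    coeffs = [0] * (b + 1)
    # row[x] = B(b - beta, a, b, x)
    row = [1]  # beta = 0: only x = 0
    coeffs[b] = 1
    for beta in range(0, b):
        i_new = b - beta - 1
        width = min(a, beta + 1)
        new_row = [0] * (width + 1)
        for x in range(0, min(a, beta) + 1):
            num = (i_new + x) * (b - beta) * row[x]
            if num % 2:
                raise RuntimeError("internal error: non-integral B coefficient")
            new_row[x] = num // 2
        if width == beta + 1:
            num = (b - beta) * (a - beta) * row[beta]
            den = beta + 1
            if num % den:
                raise RuntimeError("internal error: non-integral B coefficient")
            new_row[beta + 1] = num // den
        row = new_row
        start = 0 if i_new > 0 else 1  # exclude the i + x = 0 term
        coeffs[i_new] = sum(row[start:])
    return coeffs


def count_frs(schedule: SampleSchedule | tuple[int, ...] | list[int]) -> int:
    """Count FRS (sampled-ancestor) trees in O(m·n²) big-integer operations.

    Uses the rewritten recursion ``S(n_1,...,n_j+α) = Σ_i A(i, n_{j-1},
    n_j+α) · S(n_1,...,n_{j-1}+i)``.  For each time point the coefficient
    table at ``α = 0`` comes from :func:`_frs_initial_coeffs`; increasing the
    surplus ``α`` by one updates every coefficient in place:

        A(i, a, b+1) = C(b+1,2)·A(i, a, b)
                       + C(b+1,i)·C(a, b+1-i)·(b+1-i)!   if b-i < a,
        A(i, a, b+1) = C(b+1,2)·A(i, a, b)                otherwise,
        A(b+1, a, b+1) = 1,

    with the second summand evaluated by direct binomials and factorials.
    """
    sched = _as_schedule(schedule)
    counts = sched.counts
    if sched.m == 1:
        return count_ranked(counts[0])
    r = ranked_table(sched.n)
    # svals[i] = S(n_1, ..., n_j + i) for the current j.
    limit = sched.suffix_sums[1]
    svals = [r[counts[0] + i] for i in range(limit + 1)]
    for j in range(1, sched.m):
        a = counts[j - 1]
        nj = counts[j]
        limit = sched.suffix_sums[j + 1]
        coeffs = _frs_initial_coeffs(a, nj)
        new: list[int] = [0] * (limit + 1)
        b = nj
        while True:
            alpha = b - nj
            new[alpha] = sum(c * s for c, s in zip(coeffs, svals[: b + 1]))
            if alpha == limit:
                break
            pair = (b + 1) * b // 2
            for i in range(b + 1):
                coeffs[i] *= pair
                if b - i < a:
                    x = b + 1 - i
                    coeffs[i] += binomial(b + 1, i) * binomial(a, x) * math.factorial(x)
            coeffs.append(1)
            b += 1
        svals = new
    result = svals[0]
    if result < 0:
        raise RuntimeError("internal error: negative tree count")
    return result
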