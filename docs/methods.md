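# Methods

This note records the models, conventions and numerical choices behind
`phylocount`, in the order the modules build on each other.

## Tree spaces and their counts

**Ranked trees.** A ranked tree on a label set `X`, `|X| = n`, is a rooted
binary phylogenetic tree with an injective ranking `h` of interior nodes
consistent with ancestry (root = rank 1). These are in bijection with
coalescent histories: going back in time from `n` lineages, each of the
`n − 1` steps merges one unordered pair, giving

    R(n) = Π_{j=2}^{n} C(j,2) = n!(n−1)!/2^(n−1).

All arithmetic on counts is arbitrary-precision integer; ratios
`R(a)/R(b)` are computed as products of pair-choices `C(j,2)`, never by
dividing factorials, and no count is ever represented in floating point.

**Conventions.** `R(0) := 1` and `R(1) := 1`. The serial recursions evaluate
`R(α)` at `α = 0, 1` in denominator positions; 1 is the unique convention
under which they are consistent. `C(n,k) := 0` for `k < 0` or `k > n`.

**Fully ranked trees.** With a sample schedule `(n₁, …, n_m)` (oldest time
point first), leaves are ranked too; leaves may share a level (same sampling
time), interior nodes may not. The count `F` satisfies

    F(n₁, …, n_m) = Σ_{i=1}^{n_m} R(n_m)/R(i) · F(n₁, …, n_{m−1}+i),
    F(n) = R(n):

the `n_m` newest lineages coalesce to `i` survivors (in `R(n_m)/R(i)` ways),
which then behave as `i` additional samples at time `m−1`. `F` is *not*
permutation-invariant in the schedule (`F(2,1) = 3 ≠ 4 = F(1,2)`), so
memoization keys are whole remaining-schedule tuples.

**FRS trees (sampled ancestors).** A sampled individual may lie *on* a
lineage — a degree-2 node, or a degree-1 root — as a direct ancestor of
later samples. The recursion conditions on `i` surviving lineages of which
`j` are matched onto individuals sampled at the previous time point:

    S(…, n_m) = Σ_{i=1}^{n_m} Σ_{j=0}^{min(i, n_{m−1})}
                C(i,j) · C(n_{m−1},j) · j! · R(n_m)/R(i) · S(…, n_{m−1}+i−j).

*On the `j!` term.* The two inner binomials choose which `j` of the `i`
lineages continue into sampled ancestors and which `j` individuals those
are; because both lineages (each tagged by its descendant subtree) and
individuals (labelled) are distinguishable, each of the `j!` assignments
between the chosen sets yields a different tree. Statements of this
recursion sometimes omit the assignment factor; dropping it first bites at
schedule `(2,2)`, where the two-ancestor case admits two assignments and the
total is 37, not 36. The enumeration oracle — which constructs every FRS
tree explicitly from the definition — pins this down, and the whole test
suite enforces recursion ≡ enumeration.

## Dynamic programs for serial counts

Evaluating the `F` recursion naively costs exponential time in `m`. The fast
route sweeps time points oldest-to-newest, carrying
`F(n₁, …, n_j + α)` for every admissible surplus `α ≤ n_{j+1} + … + n_m` of
lineages crossing back past time `j`. The inner sums
`P(T) = Σ_{i≤T} F(n₁,…,n_{j−1}+i)/R(i)` are rationals; we carry the cleared
form `P(T)·R(T)` instead, which obeys the integer recurrence

    P(T+1)·R(T+1) = P(T)·R(T)·C(T+1,2) + F(n₁,…,n_{j−1}+T+1)

and *is* `F(n₁, …, n_j + α)` at `T = n_j + α`. This keeps every intermediate
an exact integer — no rational normalization (gcd) on numbers that reach
tens of thousands of digits — and costs one big-integer multiply-add per
accumulator update: O(m·n) operations overall. At `n = 2000, m = 10` the
count (a 10 868-digit integer) takes well under a second.

For `S`, the recursion is rewritten with coefficients

    A(i, a, b) = Σ_x R(b)/R(i+x) · C(i+x,x) · C(a,x) · x!,

the number of ways `b` lineages coalesce back to `i + x` lineages with `x`
of them matched onto the `a` older samples. The `i + x = 0` term is excluded
(the original sum has `i ≥ 1`; at least one ancestral lineage must survive).
Each coefficient is an integer, since `R(b)/R(i+x)` divides exactly. The
initial table at surplus `α = 0` is built by two summand recursions (one
stepping `i` at fixed `x`, one stepping the diagonal `i + x = b`), with
divisions checked exact; raising `b` by one then updates every coefficient
in place via

    A(i,a,b+1) = C(b+1,2)·A(i,a,b) + C(b+1,i)·C(a,b+1−i)·(b+1−i)!  (if b−i < a)

with the second summand evaluated by direct binomials (equivalent to, and
simpler than, carrying a separate product recursion for it), plus the
boundary `A(b+1,a,b+1) = 1`. Total cost O(m·n²); `n = 500, m = 10` runs in
about two seconds.

## Resolutions of ranked constraint trees

A constraint tree is a multifurcating ranked tree: interior nodes, labelled
`1..k` by rank, declare monophyletic groups and their ancestors' time order.
It is encoded by `(n₁, …, n_k, f)` with `n_i` leaf children of node `i` and
parent map `f(i) < i`. The count `Rʳ` of binary ranked trees embedding it
depends only on this tuple.

**Reference recursion.** States are coordinate tuples `(x₁, …, x_t)`: the
first `t` constraint nodes with `x_i` unresolved lineages each. The deepest
coalescence of a resolving tree either merges two lineages of a *candidate*
subtree — one with `x_i ≥ 2` and more than two children in the current tuple
(`x_i + α_i > 2`, `α_i` counting interior children in the restricted parent
map) — contributing `C(x_i, 2)` times the decremented state; or, when the
deepest node holds exactly its own cherry (`x_t = 2`, no interior children),
it *is* that node, which is absorbed into its parent as one lineage. Base:
the two-leaf root tuple has one resolution. The candidate rule is applied
for every node `i ≤ t` of the current tuple; restricting it to `i < t`
would, for a star tree `(n, ∅)`, leave no candidates at all and give 0
instead of `R(n)` (for the deepest node the `x_t + α_t > 2` clause already
excludes the cherry case, which the absorption move handles).

**Eligible-tuple DP.** For each level `j` the matrices
`M_{i,j} = n_i + α_i − a_{i,j}` (with `a_{i,j}` the number of interior
children of `i` ranked ≤ j) and `m_{i,j} ∈ {2, 1, 0}` (2 if `a_{i,j} = 0`,
1 if `a_{i,j} > 0 < M_{i,j}`, else 0) bound the number of subtree-`i`
branches crossing between the rank-`j` and rank-`j+1` events of any
resolving tree. A tuple is *eligible* if every coordinate lies within its
bounds. The DP enumerates the eligible tuples outright, sorts them by
coordinate sum (every recursion move lowers the sum by one), and evaluates
the same transitions bottom-up, visiting each eligible tuple exactly once —
O(n^k) states for fixed `k`. Lookups outside the eligible set contribute
zero; for valid constraint trees every referenced state is itself eligible
(the bounds are exactly the reachable ranges), which the fixture suite
confirms against the unpruned reference recursion.

## Resolutions of fully ranked constraint trees

With dated tips the constraint tree is fully ranked: `k` interior nodes with
strictly increasing levels `r(1)=1 < … < r(k) < l`, and a `k × l` *child
matrix* `n` whose entry `n_{i,j}` counts children of node `i` at level `j` —
leaf children at leaf levels plus a 1 at `(parent, r(child))` for each
interior child. `N_{c,x} = Σ_{j≥x} n_{c,j}` counts children at level `x` or
deeper. The recursion places the deepest coalescence of a resolving tree in
subtree `c` between levels `p−1` and `p` for each `p ∈ {r(k)+1, …, l}` and
each candidate `c` with `N_{c,p} ≥ 2` and more than two children overall,
reducing the matrix to `p` columns (column `p` collapses to `N_{i,p}`, minus
one for `c`); when node `k` holds exactly two children it may itself be the
deepest event, absorbing into its parent with the matrix truncated to
`r(k)` columns. Base: any two-leaf tree has exactly one resolution, whether
its leaves share a level or not.

*Encoding choice.* The public type stores the parent map explicitly and a
`leaf_matrix` of leaf children only; the interior-child entries are derived.
A single matrix-plus-ranks encoding determines the parent map only through
a column-placement convention that becomes ambiguous to read back when leaf
levels interleave with interior levels; deriving the redundant entries
removes that ambiguity and lets validation cross-check both.

**Eligible-tuple DP.** Every state reachable from the full tree agrees with
the constraint matrix on all columns before its last, so states are keyed by
`(t, q, last column)` — active nodes, level count, and collapsed lineage
counts. Bounds per level: `M_{i,j} = N_{i,j+1}`, and

    m_{i,j} = max(0, 2 − c_{i,j}),

where `c_{i,j}` counts **all** children of node `i` (leaf or interior) with
level ≤ j. When every leaf sits at the deepest level this reduces to the
classical interior-children-only three-case rule above; with interleaved
leaf levels the leaf terms are necessary — a node whose children all lie at
early levels legitimately has zero lineages crossing later gaps, and an
interior-only rule would exclude reachable states with nonzero counts (the
already-binary tree `r=(1,2)`, node 2 with two level-3 leaves, root with a
level-4 leaf, is the smallest example: its own full-tree state violates the
interior-only bound). The lower bound used is exactly the
at-least-two-children condition for a state to resolve to anything at all.
States are enumerated outright per `(t, q)`, sorted by matrix sum (reduction
moves lower it by one, absorption by two), and evaluated bottom-up;
O(m²·n^k) for fixed `k`. The proposal-function formulation (growing states
by adding one leaf or the next interior node, gated by an extension
predicate) generates the same state space; direct enumeration over the
closed-form bounds was chosen because it makes the single-visit contract
trivially auditable. The `addone`/`addconstraint`/`ext` machinery is
therefore implicit in the per-column bounds rather than implemented as
separate functions.

## Enumeration oracle

All counting routes are validated against literal enumeration. Trees are
canonical nested tuples — children sorted, ranks explicit, labels strings —
so set membership is isomorphism-free without graph machinery. Enumeration
is by backward coalescence; every tree arises from exactly one choice
sequence, and results are deduplicated defensively anyway. For FRS trees,
each sampling event may also place any subset of that group's individuals
injectively onto distinct active lineages (one per lineage per time point:
two stacked same-level degree-2 nodes would violate strict ancestor
monotonicity); a placement that finishes on top of the tree is the labelled
degree-1 root.

Resolution sets are produced two independent ways: (i) enumerate the whole
ranked space and keep trees in which every constraint clade appears as an
exact clade with images in constraint-rank order (for fully ranked
constraints, additionally with level-equality classes preserved and the
joint leaf/interior level order respected); (ii) constrained backward
coalescence, pruning any merge whose leafset straddles a constraint clade,
strictly swallows an unrealized clade, or realizes clades out of reverse
rank order. The two strategies agree on every fixture, which guards the
embedding test and the generator against correlated mistakes. Enumeration
refuses instances above small caps (7 leaves ranked/fully ranked, 6 for FRS
and resolutions) unless explicitly overridden; the spaces grow as `R(n)`
or faster.

## Fixtures

Random constraint trees are generated deterministically per seed, starting
with forced edge cases (two-leaf trees, stars, fully binary caterpillars)
and continuing with rejection sampling under the size caps: parent maps are
uniform rank-decreasing; each node receives the leaves needed to reach two
children; every leaf level is made non-empty; remaining leaves are sprinkled
geometrically. The generator emulates the *combinatorial* variety of
constraint shapes (multifurcation widths, nesting depths, interleaved
levels) — it makes no claim about the distribution of constraints arising
from real fossil calibrations, so passing fixtures demonstrates correctness
of the counts, not realism of any biological sampling process.

## Problem sizes and tolerances

Everything here is exact integer arithmetic: every test asserts equality,
and there are no tolerances to tune. The suite's problem sizes — oracle
sweeps to 7 samples (2700–56 700 trees per instance), 200 random ranked and
120 fully ranked constraint fixtures, identity checks to `n = 200`, smoke
runs at `n = 2000` (F) and `n = 500` (S) — were chosen so the whole suite
completes in about a minute on one core while still crossing every
structural threshold (first sampled-ancestor matchings at `(2,2)`, first
interleaved-level corrections, first multi-candidate levels).

## Known limitations

* Resolution counting for *FRS* constraint trees (constraints combined with
  sampled ancestors) is out of scope; the space is defined but no counting
  recursion is implemented.
* The eligible-tuple DPs are exponential in the number of constraints `k`
  (O(n^k)); they are practical for the small `k` typical of fossil
  calibrations, not for dense constraint sets.
* Enumeration oracles are for verification only; they refuse `n` beyond
  their caps by design.
* Complexity statements are checked empirically as timing smoke tests, not
  proven by the test suite.
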