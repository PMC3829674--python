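# phylocount

Exact counting of phylogenetic tree spaces that arise with serially sampled
data, sampled ancestors, and clade constraints — in arbitrary-precision
integer arithmetic, with a library API, a thin command line, and exhaustive
enumeration oracles for verification.

## The problem

Bayesian phylogenetic inference places prior distributions over tree
topologies. When a uniform prior over topologies is used, its density is
`1 / (number of trees)`, so the size of the tree space is a normalizing
constant that sometimes must be computed explicitly — for instance when
fossil calibrations weight the marginal density of a calibration-node age by
the number of topologies compatible with the imposed constraints.

For `n` contemporaneous samples the space of **ranked trees** (rooted binary
trees with a total time-order on interior nodes) has the closed form

    R(n) = n! (n−1)! / 2^(n−1).

Serial (heterochronous) sampling, sampled ancestors and monophyly
constraints each change the space, and no closed forms are known.
`phylocount` computes, exactly:

* **F(n₁, …, n_m)** — fully ranked trees, where the sample schedule
  `(n₁, …, n_m)` gives the number of individuals sampled at each of `m` time
  points (oldest first) and leaves are ranked by sampling time. Defined by

      F(n₁, …, n_m) = Σ_{i=1}^{n_m} R(n_m)/R(i) · F(n₁, …, n_{m−1} + i),
      F(n) = R(n),

  and computed by an O(m·n) dynamic program.
* **S(n₁, …, n_m)** — fully ranked trees with **sampled ancestors** (FRS
  trees): an earlier sample may sit on a lineage as a degree-2 node, being a
  direct ancestor of later samples. Computed by an O(m·n²) dynamic program.
  (The recursion multiplicity includes the `j!` assignments of the `j`
  ancestral samples onto the `j` chosen lineages; see
  `docs/methods.md`.)
* **Rʳ(n₁, …, n_k, f)** — binary ranked trees *resolving* a multifurcating
  ranked **constraint tree**, encoded by leaf counts per interior node and
  the parent map `f`. Computed by a dynamic program over *eligible tuples*
  bounded by lineage-count matrices `m` and `M`; O(n^k) for fixed `k`.
* **Fʳ(n, r)** — fully ranked trees resolving a **fully ranked constraint
  tree** (constraints plus dated tips), the generalization of the above to
  a `k × l` leaf-level matrix `n` and interior-rank map `r`.

Every counter exists twice — a reference recursion (`*_naive`) transcribing
the defining equations, and the fast dynamic program — and both are checked
against literal enumeration of the tree space on small instances
(`phylocount.oracle`).

## Worked example

Seven taxa with two constrained clades, one nested — the constraint tree
`(0,2,3,2,{(2,1),(3,1),(4,2)})`: the root (rank 1) has subtrees 2 and 3;
subtree 2 holds two leaves and the nested cherry 4; subtree 3 holds three
leaves.

```python
>>> from phylocount import parse_constraint_tuple, count_resolutions, count_ranked
>>> ctree = parse_constraint_tuple("(0,2,3,2,{(2,1),(3,1),(4,2)})")
>>> count_resolutions(ctree)
54
>>> count_ranked(7)
56700
```

Only 54 of the 56 700 ranked trees on 7 leaves satisfy the constraints: a
uniform prior restricted to the constrained space weights each tree by
1/54, three orders of magnitude away from 1/56700.

The same from the shell, with the reference recursion cross-checked:

```console
$ phylocount resolutions --tree fig_tree.txt --check
54
$ phylocount fully-ranked 5 3 2
3317144400
$ phylocount frs 2 2
37
$ phylocount enumerate frs 2 1
5
```

`examples/` contains one short narrative script per capability
(`python examples/count_constraint_resolutions.py` prints the run above with
commentary).

### Input formats

Constraint trees are accepted as compact tuples
(`(0,2,3,2,{(2,1),(3,1),(4,2)})`), JSON
(`{"leaf_counts": [...], "parents": {"2": 1}}`) or annotated Newick in which
interior labels are ranks and branch lengths are absent
(`((a,b,(c,d)4)2,(e,f,g)3)1;` — leaf names are arbitrary and discarded).
Fully ranked constraint trees are JSON
(`{"ranks":[1],"leaf_matrix":[[0,2,1]],"parents":{}}`) or Newick with
`#level` suffixes on leaf names (`(l1#2,l2#2,l3#3)1;`). All counts print in
full decimal; they grow super-exponentially.

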