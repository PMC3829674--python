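"""Count binary ranked trees compatible with clade constraints.

A constraint tree records prior knowledge: which groups are monophyletic and
in what order their common ancestors occurred.  Counting its binary ranked
resolutions gives the normalizing constant for a uniform prior restricted to
the constrained tree space.
"""

from phylocount import (
    bounds_matrices,
    count_ranked,
    count_resolutions,
    count_resolutions_naive,
    parse_constraint_tuple,
)

# root (rank 1) with two constrained subclades: node 2 (two leaves + a nested
# cherry, node 4) and node 3 (three leaves); 7 leaves in total
ctree = parse_constraint_tuple("(0,2,3,2,{(2,1),(3,1),(4,2)})")
print(f"constraint tree: k={ctree.k} clade ancestors, n={ctree.n} leaves")

count = count_resolutions(ctree)
print(f"ranked resolutions:       {count}")
print(f"reference recursion:      {count_resolutions_naive(ctree)}")
print(f"unconstrained R({ctree.n}):      {count_ranked(ctree.n)}")
print(f"fraction of tree space:   {count}/{count_ranked(ctree.n)}")

b = bounds_matrices(ctree)
print(f"lineage bounds below the rank-2 event: subtree 2 crosses between "
      f"{b.entry('m', 2, 2)} and {b.entry('M', 2, 2)} lineages")

# 54 of the 56700 ranked trees on 7 leaves satisfy the constraints - the
# prior weight of any single compatible topology is 1/54, not 1/56700.
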