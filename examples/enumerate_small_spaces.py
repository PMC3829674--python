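"""Enumerate small tree spaces explicitly and confirm the closed forms.

The enumeration oracle constructs every tree by backward coalescence; on
small label sets this is feasible and provides ground truth for the counting
recursions.
"""

from phylocount import count_frs, count_fully_ranked, count_ranked, write_tree_newick
from phylocount.oracle import enumerate_frs, enumerate_fully_ranked, enumerate_ranked

for n in range(2, 6):
    trees = enumerate_ranked([chr(ord("A") + i) for i in range(n)])
    print(f"ranked trees on {n} leaves: {len(trees)} (closed form R({n}) = {count_ranked(n)})")

print()
sched = (2, 1)
for tree in sorted(enumerate_fully_ranked(sched)):
    print("F(2,1) tree:", write_tree_newick(tree))
print(f"total {count_fully_ranked(sched)} - interior labels are time levels, "
      "leaf suffixes '#level' give sampling levels")

print()
for tree in sorted(enumerate_frs((1, 1))):
    print("S(1,1) tree:", write_tree_newick(tree))
print(f"total {count_frs((1, 1))} - the unary node is a sampled ancestor")
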