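"""Count genealogies that allow sampled ancestors.

With dense sampling (small populations, intense outbreak surveillance, or
fossils along a lineage) an earlier sample may be the *direct ancestor* of a
later one: it sits on a lineage as a degree-2 node instead of ending a
branch.  The FRS count S includes every placement of such ancestors.
"""

from phylocount import count_frs, count_fully_ranked

for schedule in [(1, 1), (2, 1), (3, 2), (2, 2, 2)]:
    s = count_frs(schedule)
    f = count_fully_ranked(schedule)
    print(f"schedule {schedule}: S = {s:6d}  F = {f:6d}  ancestor placements = {s - f}")

# S >= F always: the fully ranked trees are exactly the FRS trees with zero
# sampled ancestors.  For (1,1) the two trees are "earlier sample is a
# sibling lineage" and "earlier sample is the direct ancestor".
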