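"""Count fully ranked resolutions of a constraint tree with dated tips.

When constraints and serial sampling occur together, the constraint tree is
itself fully ranked: clade ancestors and sampling times share one time
order.  The resolution count then lives in fully-ranked tree space.
"""

from phylocount import (
    count_fr_resolutions,
    count_fr_resolutions_naive,
    count_fully_ranked,
    parse_fr_constraint,
)

# one clade ancestor (the root, level 1); two leaves sampled at level 2 and
# one more at level 3 - i.e. the star constraint over schedule (2, 1)
star = parse_fr_constraint('{"ranks": [1], "leaf_matrix": [[0, 2, 1]], "parents": {}}')
print(f"star over schedule (2,1): {count_fr_resolutions(star)} resolutions "
      f"(= F(2,1) = {count_fully_ranked((2, 1))})")

# a nested constraint: root (level 1) holds subtree 2 (level 2) and a leaf
# sampled at level 5; subtree 2 holds two leaves sampled at level 3 and one
# at level 4
nested = parse_fr_constraint(
    '{"ranks": [1, 2], "leaf_matrix": [[0,0,0,0,1],[0,0,2,1,0]], "parents": {"2": 1}}'
)
fast = count_fr_resolutions(nested)
print(f"nested constraint tree:   {fast} resolutions "
      f"(reference: {count_fr_resolutions_naive(nested)})")

# the star imposes no constraint beyond the root, so its resolutions are all
# F(2,1) = 3 fully ranked trees; the nested clade cuts that space down.
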