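"""Count tree topologies for serially sampled data.

Five viral genomes sampled in 2019, three more in 2021, two more in 2023:
how many time-ordered binary genealogies are compatible with that sampling
schedule?
"""

from phylocount import count_fully_ranked, count_fully_ranked_naive, count_ranked

schedule = (5, 3, 2)  # oldest sampling time first

fast = count_fully_ranked(schedule)
reference = count_fully_ranked_naive(schedule)
contemporaneous = count_ranked(sum(schedule))

print(f"sample schedule (oldest first): {schedule}")
print(f"fully ranked trees F{schedule}: {fast}")
print(f"reference recursion agrees:    {reference}")
print(f"R({sum(schedule)}) if all contemporaneous: {contemporaneous}")

# F counts trees whose leaves are ranked by sampling time; it is larger than
# R(10) here because serial sampling lets coalescences interleave with
# sampling events, and a uniform tree-topology prior must divide by F, not R.
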