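"""Collapsing per-sample RNA-seq IM calls to per-gene annotations.

Expression-based isoform calls come per (gene, individual, tissue).
They collapse in two steps: a gene has IM for an individual if it has
IM in at least one tissue; across individuals, either "any" (at least
one individual) or the stricter "each" (every individual).
"""

from imco import SampleIMTable, collapse_individuals, collapse_tissues

table = SampleIMTable.from_records([
    # gene, individual, tissue, has_im
    ("gA", "ind1", "liver", False), ("gA", "ind1", "brain", True),
    ("gA", "ind2", "liver", True),  ("gA", "ind3", "brain", False),
    ("gB", "ind1", "liver", True),  ("gB", "ind2", "brain", True),
    ("gB", "ind3", "liver", True),
    ("gC", "ind1", "liver", False), ("gC", "ind2", "brain", False),
])

per_individual = {ind: collapse_tissues(table, ind) for ind in table.individuals}
for ind, calls in per_individual.items():
    print(f"{ind}: {calls}")
print("any :", collapse_individuals(per_individual, "any"))
print("each:", collapse_individuals(per_individual, "each"))
# "each" is always a subset of "any": gB has IM in every individual, gA
# only in some, gC in none.
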