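"""Unbalanced allele counts and the concatenation plan.

Accession A yielded a single ITS sequence but two phased ETS variants.
The injective pairing matches the single allele to one variant for the
distance computation; the concatenation plan then repeats the single
sequence against BOTH variants, the standard rule for building a
combined matrix from unbalanced markers.
"""

from phaselink import SearchConfig, concatenation_plan, link_alleles, parse_newick

tree_its = parse_newick("((A|s:1,B|0:1)0.9:1,(B|1:1,C|d:1)0.9:1);")
tree_ets = parse_newick("(((A|0:1,B|0:1)0.9:1,(A|1:1,B|1:1)0.9:1)0.9:1,C|d:1);")

result = link_alleles(tree_its, tree_ets, SearchConfig(seed=0))
plan = concatenation_plan(result)

print(f"score: {result.score}")
print(plan.to_string(index=False))
print()
print(
    "Accession A appears in two rows: its single marker-1 sequence is paired\n"
    "with both marker-2 variants.  Collapsed mono-accession allele groups\n"
    "(none here) would be expanded back to their representative allele with\n"
    "the group members listed in the members_* columns."
)
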