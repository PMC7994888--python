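"""Plain and weighted rooted Robinson-Foulds distances.

Two discordant quartets: every internal branch has length 0.1, one
clade has support 0.9, the rest 1.0.  The four clades of the symmetric
difference contribute 0.09 + 0.1 + 0.1 + 0.1 = 0.39.  Re-running with
all supports at 0.4 shows the <50% support-removal rule zeroing the
distance.
"""

from phaselink import MetricConfig, parse_newick, rf_distance, weighted_rf_distance

a = parse_newick("((a:1,b:1)0.9:0.1,(c:1,d:1)1.0:0.1);")
b = parse_newick("((a:1,c:1)1.0:0.1,(b:1,d:1)1.0:0.1);")

print(f"plain RF  (topology only): {rf_distance(a, b)}")
print(f"weighted RF (length x support): {weighted_rf_distance(a, b)}")

a_low = parse_newick("((a:1,b:1)0.4:0.1,(c:1,d:1)0.4:0.1);")
b_low = parse_newick("((a:1,c:1)0.4:0.1,(b:1,d:1)0.4:0.1);")
print(f"weighted RF, all supports 0.4: {weighted_rf_distance(a_low, b_low)}")

print(f"weighted RF, threshold 0.3: "
      f"{weighted_rf_distance(a_low, b_low, MetricConfig(support_threshold=0.3))}")
print()
print(
    "The plain distance counts discordant clades (4); the weighted distance\n"
    "sums branch length x support over them, and clades below the support\n"
    "threshold (default 0.5) are removed from the calculation entirely."
)
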