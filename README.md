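# phaselink

Match phased alleles of two multi-copy markers across their gene trees.

## The problem

Phased sequence variants ("alleles") of linked multi-copy markers — e.g. the
ITS and ETS spacers of the 45S nuclear rDNA cistron — often cannot be
connected to each other directly: conserved sequence between the regions
removes the linking polymorphisms, and allele loss or unequal homogenization
leaves the markers with different allele counts per sample. Before the
markers can be concatenated (or their trees compared leaf-by-leaf), one must
decide which ITS allele of each accession belongs with which ETS allele.

phaselink recovers that correspondence from the two gene trees alone. For a
candidate per-accession allele pairing ("combination") it relabels matched
leaves to a common name and scores the resulting trees with rooted
Robinson–Foulds distances; the best combination is the one making the trees
most similar. The search is two-phase:

1. **local** — seeded coordinate descent under the plain (topology-only) RF
   distance retains, for each accession, every locally optimal pairing;
2. **global** — the Cartesian product of the retained sets is scanned
   exhaustively under a weighted rooted RF distance in which each discordant
   clade contributes `branch length × child-node support`, and clades below
   50% support are removed from the calculation.

Trees are first pruned to shared accessions, and clades made up exclusively
of one accession's alleles are collapsed to a single branch (they are
invariant under relabeling and carry no signal). All tied optima are
reported; each accession receives a verdict of `keep`, `swap`, or
`equivocal`.

## Worked example

Accessions A and B carry two phased alleles per marker, C a single direct
sequence; in the second tree B's labels were crossed:

```python
from phaselink import SearchConfig, concatenation_plan, link_alleles, parse_newick

tree_its = parse_newick(
    "((((A|0:1.0,B|0:1.0)0.95:0.5,B|1:1.5)0.9:0.5,A|1:2.0)0.9:0.5,C|d:2.5);"
)
tree_ets = parse_newick(
    "((((A|0:1.0,B|1:1.0)0.95:0.5,B|0:1.5)0.9:0.5,A|1:2.0)0.9:0.5,C|d:2.5);"
)
result = link_alleles(tree_its, tree_ets, SearchConfig(seed=1))
print(result.score, result.verdicts)
print(concatenation_plan(result).to_string(index=False))
```

prints

```
0.0 {'A': 'keep', 'B': 'swap', 'C': 'keep'}
accession allele_a allele_b members_a members_b  equivocal
        A        0        0                          False
        A        1        1                          False
        B        0        1                          False
        B        1        0                          False
        C        d        d                          False
```

The score of 0 means a relabeling exists under which the two trees agree
perfectly, and the `swap` verdict says B's marker-2 alleles must be
exchanged before concatenation. The plan lists one row per allele pair to
concatenate; a single sequence facing two variants of the other marker
appears in two rows (see `examples/04_unbalanced_accessions.py`).

More narrative scripts live in `examples/`: tree distances and the support
filter (`02`), simulation and recovery under noise (`03`).

## Command line

A thin CLI wraps the same functions:

```sh
phaselink link --tree-a its.nwk --tree-b ets.nwk --seed 1 --out-prefix run
phaselink rf --tree-a its.nwk --tree-b ets.nwk
phaselink simulate --n 12 --nni 2 --seed 1 --out-prefix synthetic
```

`link` writes the full result as JSON plus verdict and concatenation tables
as TSV; `rf` prints the plain and weighted distances; `simulate` writes a
synthetic tree pair with its ground-truth pairing table. Leaf labels are
`accession|allele` by default (`--delimiter`, `--label-regex` override; a
label without a delimiter is treated as a direct sequence).

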