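# Methods

## The problem

Multi-copy nuclear markers such as the rDNA spacers ITS and ETS sit in one
tandem array, yet after read phasing the reconstructed sequence variants
("alleles") of the two regions cannot always be connected: conserved
intervening sequence (the 18S in the ITS/ETS case) removes the linking
polymorphisms, and allele loss or unequal homogenization leaves the two
markers with different allele counts for the same accession. Building a
concatenated matrix, or even comparing the two gene trees leaf-by-leaf, first
requires deciding *which allele of marker A corresponds to which allele of
marker B* within every accession.

phaselink treats this as a combinatorial optimization over rooted gene trees.
A **combination** assigns, for each accession shared by the two trees, an
injective map from its smaller allele set into its larger one. The objective
of a combination is the distance between the two trees after relabeling
matched leaves to a common name; the best combinations are those producing
the most similar trees. The method assumes the correspondence signal is
*positional*: a correctly matched allele pair occupies mirror positions in
the two trees because the two regions share one evolutionary history.

## Preprocessing

1. **Prune** both trees to the accessions they share. Degree-2 nodes created
   by leaf removal are spliced out with their two branch lengths summed; the
   spliced node's support is discarded (it annotated a clade that no longer
   exists).
2. **Collapse** every maximal clade whose leaves all belong to one accession.
   Such coalescent allele groups are invariant under relabeling — swapping
   labels inside an exclusive clade yields an isomorphic tree — so they carry
   no information for the search and only inflate the combinatorial load.
   The clade is replaced by a single leaf with a synthetic code `g<i>`, whose
   branch length is the clade's stem branch plus the branch of the *most
   basal* member (the leaf attached closest to the clade root; ties broken
   lexicographically by allele code). The stem+basal reading preserves the
   collapsed group's depth in the tree; since "most basal" admits more than
   one reading, this one is fixed here as the package's convention and
   recorded in the collapse report together with all member codes.

Unbalanced accessions are handled at relabeling time in one of two modes:
**prune** (default) removes unmatched alleles of the larger side before the
distance is computed — the plain RF distance is defined on identical leaf
sets and pruning introduces no artificial zero-length structure — while
**duplicate** replaces an allele matched to *m* partners by *m* leaves on a
zero-length cherry. For an accession with two or more alleles on the smaller
side, the unmatched larger-side alleles are distributed round-robin over the
sorted smaller-side codes; with a single allele on the smaller side this
reduces to the familiar rule of concatenating a single sequence with both
variants of the other region.

## The two objectives

Both distances operate on non-trivial rooted clades (leaf subsets of size
≥ 2 and < all leaves); the root clade and single leaves never contribute.

* **Plain rooted Robinson–Foulds**: the cardinality of the symmetric
  difference of the two clade sets. Topology only; used in the local phase
  because it is cheap and ties are exact integers.
* **Weighted rooted Robinson–Foulds**: each clade of the topological
  symmetric difference contributes `branch length × child-node support`,
  measured on its own tree (by definition it is absent from the other), and
  any clade with support below the threshold (default 0.5, i.e. <50%) is
  removed from the calculation. Support exactly at the threshold is
  retained. This makes disagreement on long, well-supported branches
  expensive and poorly supported conflict free, and it guarantees two
  properties the package tests rely on: the distance is zero whenever the
  topologies agree, and it is non-increasing in the threshold.

Missing annotations are governed by two policies. A clade without a support
value acts as fully supported by default (`retain-as-1`) so that nodes
produced by preprocessing do not silently leave the objective; `drop`
excludes them instead. A missing branch length contributes weight 0 by
default (`as-0`); `as-1` degenerates to support-only weighting for trees
without lengths. Supports above 1 anywhere in an input tree are read as
percentages and normalized to [0, 1]; mixed scales trigger a warning.

## The two-phase search

The number of combinations is the product over accessions of
`|larger|!/(|larger|−|smaller|)!` and grows exponentially, so the search
runs in two phases.

**Local phase (plain RF).** For each restart, every accession receives a
random pairing; accessions are then visited in seeded random order, and for
each focal accession all of its pairings are scored with the others held
fixed. *All* minimizers are recorded, and the focal assignment moves to a
minimizer. Sweeps repeat to a fixed point (capped at `max_sweeps`, default
20). Retained sets are unioned over restarts (default 10), and the canonical
identity pairing — sorted allele codes aligned element-wise — is always
force-included, so "keep everything as named" is always expressible and the
final optimum can never be worse than not swapping. A single restart
reproduces the bare coordinate-descent behaviour; the default of 10 restarts
only ever enlarges the candidate pool.

**Global phase (weighted RF).** The Cartesian product of the retained sets
is scanned exhaustively (capacity-guarded at `global_cap`, default 10⁶
combinations, with a clear error advising a tighter local phase). All global
minima within an absolute score tolerance of 1e-9 are kept.

**Verdicts.** Per accession, the set of pairings occurring among the global
optima determines the call: one pairing equal to the canonical identity →
`keep`; one non-identity pairing → `swap`; two or more distinct pairings →
`equivocal`. Any ambiguity is reported, never silently resolved — ties are
genuine features of the data (e.g. an allele pair attached symmetrically at
the root) and downstream resolution needs external evidence.

## The synthetic-data generator

`make_paired_instance` emulates the target data: one pure-birth (Yule,
unit-rate, exponential waiting times) accession tree is expanded twice into
allele trees sharing one allelic history, and tree B is then degraded.

* **Allele counts** per accession are drawn once and shared by both markers
  (they reside in one array); the default distribution is 1: 0.2, 2: 0.6,
  3: 0.1, 4: 0.1, capped at four — the maximum two rounds of phasing can
  produce. Codes follow the two-round scheme: `s`; `0/1`; `0, 1.0, 1.1`;
  `0.0, 0.1, 1.0, 1.1`.
* **Coalescence.** By default 60% of two-allele accessions are
  *non-coalescent*: allele 1 attaches one node deeper in the backbone,
  bracketing the accession's sister lineage. The rest form exclusive allele
  clades at the accession's position, with within-accession branch lengths
  below 10% of tree height. Real rDNA alleles are often, but not always,
  coalescent; the non-coalescent fraction is what makes matching informative
  at all, because a swap inside an exclusive clade is undetectable *in
  principle*.
* **Planted truth.** Half of the non-coalescent two-allele accessions
  (default `planted_swap_fraction=0.5`) have their labels 0/1 exchanged in
  tree B; the permutation is recorded as ground truth. Swaps are planted
  only where a truth is well-defined (see above).
* **Noise.** Tree B receives `n_nni` random nearest-neighbor interchanges
  (each changes at most one clade per direction), an independent
  lognormal(0, σ) factor on every branch length, and supports drawn from
  the support model (default uniform on [0.5, 1], so no clade is removed by
  the filter unless the user lowers the range). Tree A stays fixed — the
  objective is symmetric, so one noisy tree loses no generality and keeps
  truth bookkeeping simple.

What the generator does **not** emulate: incomplete lineage sorting or any
explicit coalescent process, *in-silico* recombination within a marker,
sequence-level evolution, alignment error, or unbalanced allele counts
between markers (a ground-truth pairing for those is ill-defined; unbalanced
accessions are exercised with hand-built fixtures instead). Passing recovery
tests therefore demonstrates that the search recovers positional signal
under topological and length noise — not that real rDNA datasets contain
that signal.

## Numerical and determinism choices

* Score ties at absolute tolerance 1e-9 (plain RF ties are exact integers).
* Branch lengths serialize to 12 significant digits; Newick parse → write →
  parse is the identity on topology, labels, lengths and supports. Supports
  are written on the percentage scale by default (bootstrap convention).
* Restart *r* seeds a stdlib `Random(seed + 7919·r)`; the simulator derives
  per-stage child seeds from a single `numpy` generator. Identical inputs,
  seed and configuration give byte-identical serialized results.
* Degenerate inputs: single-allele accessions pass through as trivial
  pairings; a fully collapsed accession is never enumerated; two-leaf trees
  have empty clade sets and distance 0; trees sharing no accession raise
  immediately.

## Validation problem sizes

The shipped validation suite runs the pipeline on six-accession, two-allele
instances (search space 2⁶ = 64 combinations), where an exhaustive scan of
*all* combinations is an exact, independent oracle: 100 seeded instances for
heuristic-vs-oracle agreement and noise-free truth recovery, 50 seeds per
noise level for the degradation curve, and 200 random tree pairs (≤ 12
leaves) against a bitmask clade-enumeration oracle for the metric laws.
These sizes give the brute-force cross-checks exact coverage while keeping
the whole suite quick on a laptop.

## Known limitations

* Exactly two markers; no simultaneous matching of three or more loci.
* The local phase is a heuristic: retained sets can in principle miss the
  weighted-RF optimum (the global scan is exact only over the retained
  product). Restarts mitigate this; on the validation sizes agreement with
  the full brute force is complete.
* Rooted-tree semantics throughout; input trees must be rooted sensibly
  (a `--outgroup` convenience reroot is available in the CLI).
* The collapse length rule and the duplicate-mode round-robin assignment are
  package conventions chosen among several defensible readings of standard
  practice; both are deterministic and documented above.
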