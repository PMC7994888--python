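"""Paired allele-tree simulator with known ground-truth pairings.

The generator emulates the situation the matcher is built for: two
gene trees (markers A and B, think ITS and ETS) over the same set of
accessions, each accession contributing one to four phased alleles
that share one allelic history across the markers.  A known fraction
of two-allele accessions has its labels swapped in tree B — the
planted truth the matcher should recover — and tree B can additionally
be degraded with topological (NNI) and branch-length noise.

Alleles of an accession are either *coalescent* (an exclusive clade at
the accession's position — such groups collapse during preprocessing
and carry no matching signal; swapping inside one yields an isomorphic
tree, so no swap can meaningfully be planted there) or
*non-coalescent*: the second allele attaches one node deeper in the
backbone, bracketing the accession's sister lineage, which is what
makes a label swap detectable.  Real rDNA alleles are often, but not
always, coalescent; ``noncoalescent_fraction`` controls the mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import PhaselinkError
from .matcher import Pairing
from .tree_io import AlleleLabel, LabeledTree, Node

__all__ = [
    "SimConfig",
    "SyntheticPair",
    "simulate_accession_tree",
    "expand_alleles",
    "perturb_tree",
    "make_paired_instance",
]

# allele code sets of the two-round phasing scheme, by count
_CODES = {
    1: ("s",),
    2: ("0", "1"),
    3: ("0", "1.0", "1.1"),
    4: ("0.0", "0.1", "1.0", "1.1"),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated tree pair.

    ``allele_count_distribution`` gives the probability of an accession
    carrying 1-4 alleles (shared by both markers: the two markers
    reside in one tandem array and follow one allelic history; four is
    the cap of two phasing rounds).  ``n_nni`` random nearest-neighbor
    interchanges and a lognormal branch-length jitter of scale
    ``length_jitter_sigma`` are applied to tree B only.
    ``support_model`` is either ``("fixed", v)`` or
    ``("uniform", lo, hi)`` on [0, 1].  Swaps are planted on a
    ``planted_swap_fraction`` of the non-coalescent two-allele
    accessions, where a ground truth is well-defined.
    """

    n_accessions: int = 12
    allele_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.6, 3: 0.1, 4: 0.1}
    )
    n_nni: int = 0
    length_jitter_sigma: float = 0.0
    support_model: tuple = ("uniform", 0.5, 1.0)
    planted_swap_fraction: float = 0.5
    noncoalescent_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise PhaselinkError("need at least two accessions to build a tree")
        if any(k not in (1, 2, 3, 4) for k in self.allele_count_distribution):
            raise PhaselinkError("allele counts are capped at 4 per marker per accession")
        total = sum(self.allele_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise PhaselinkError("allele count probabilities must sum to 1")
        if not 0.0 <= self.planted_swap_fraction <= 1.0:
            raise PhaselinkError("planted_swap_fraction must lie in [0, 1]")
        if self.n_nni < 0 or self.length_jitter_sigma < 0:
            raise PhaselinkError("noise levels must be non-negative")


@dataclass
class SyntheticPair:
    """Two allele trees plus the planted per-accession truth."""

    tree_a: LabeledTree
    tree_b: LabeledTree
    truth: dict[str, Pairing]
    noise: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_accession_tree(n: int, seed: int = 0) -> LabeledTree:
    """Pure-birth (Yule) rooted binary tree with ``n`` accession leaves.

    Exponential waiting times at unit speciation rate per lineage;
    leaves are labeled ``acc1`` .. ``accN`` in tree order and carry the
    direct-sequence allele code ``d``.  Deterministic per seed.
    """
    if n < 2:
        raise PhaselinkError("a Yule tree needs n >= 2 leaves")
    rng = np.random.default_rng(seed)
    root = Node(children=[Node(length=0.0), Node(length=0.0)])
    active = list(root.children)
    while len(active) < n:
        t = rng.exponential(1.0 / len(active))
        for leaf in active:
            leaf.length += t
        idx = int(rng.integers(len(active)))
        split = active.pop(idx)
        split.children = [Node(length=0.0), Node(length=0.0)]
        active.extend(split.children)
    t = rng.exponential(1.0 / n)
    for leaf in active:
        leaf.length += t
    tree = LabeledTree(root)
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.allele = AlleleLabel(f"acc{i}", "d")
    return tree


def _allele_clade(codes: tuple[str, ...], eps: float, rng: np.random.Generator) -> Node:
    """Hierarchical allele clade mirroring the two-round phasing scheme."""

    def leaf(code: str) -> Node:
        return Node(length=float(rng.uniform(0.2, 1.0)) * eps,
                    allele=AlleleLabel("_", code))

    def join(*children: Node) -> Node:
        return Node(children=list(children), length=float(rng.uniform(0.2, 1.0)) * eps)

    if len(codes) == 1:
        return leaf(codes[0])
    if len(codes) == 2:
        return join(leaf(codes[0]), leaf(codes[1]))
    if len(codes) == 3:
        return join(leaf("0"), join(leaf("1.0"), leaf("1.1")))
    return join(join(leaf("0.0"), leaf("0.1")), join(leaf("1.0"), leaf("1.1")))


def expand_alleles(
    tree: LabeledTree,
    config: SimConfig,
    marker: str = "A",
    seed: Optional[int] = None,
    counts: Optional[dict[str, int]] = None,
    noncoalescent: Optional[set[str]] = None,
) -> tuple[LabeledTree, dict[str, list[str]]]:
    """Replace each bare accession leaf by a clade of phased alleles.

    ``counts`` (allele count per accession) and ``noncoalescent`` (the
    two-allele accessions whose second allele attaches one node deeper
    in the backbone) may be supplied so both markers share one allelic
    history; otherwise they are drawn here.  Within-accession branch
    lengths are kept small (< 10% of tree height).  Returns the
    expanded tree and a registry of allele codes per accession.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = tree.copy()
    if counts is None:
        ks = sorted(config.allele_count_distribution)
        ps = [config.allele_count_distribution[k] for k in ks]
        counts = {
            leaf.allele.accession: int(rng.choice(ks, p=ps)) for leaf in out.leaves()
        }
    if noncoalescent is None:
        noncoalescent = {
            acc
            for acc, k in counts.items()
            if k == 2 and rng.random() < config.noncoalescent_fraction
        }
    eps = 0.04 * max(out.height(), 1e-6)
    registry: dict[str, list[str]] = {}

    parent_of = {c: p for p in out.preorder() for c in p.children}
    for leaf in out.leaves():
        acc = leaf.allele.accession
        codes = _CODES[counts[acc]]
        registry[acc] = list(codes)
        if acc in noncoalescent and counts[acc] == 2:
            # allele 0 stays at the accession's position; allele 1 is
            # grafted above the parent so the pair brackets the sister
            # lineage instead of forming an exclusive cherry
            leaf.allele = AlleleLabel(acc, codes[0])
            other = Node(length=float(rng.uniform(0.2, 1.0)) * eps,
                         allele=AlleleLabel(acc, codes[1]))
            parent = parent_of[leaf]
            grandparent = parent_of.get(parent)
            if grandparent is None:  # parent is the root: attach there
                parent.children.append(other)
            else:
                stem = parent.length if parent.length is not None else 0.0
                mid = Node(children=[parent, other], length=stem / 2.0,
                           support=None)
                parent.length = stem / 2.0
                grandparent.children[grandparent.children.index(parent)] = mid
                parent_of[parent] = mid
                parent_of[mid] = grandparent
            parent_of[other] = parent_of[leaf] if grandparent is None else mid
        else:
            clade = _allele_clade(codes, eps, rng)
            clade.length = leaf.length
            if clade.is_leaf:
                clade.allele = AlleleLabel(acc, codes[0])
            else:
                for sub in LabeledTree(clade).leaves():
                    sub.allele = AlleleLabel(acc, sub.allele.allele_code)
            parent = parent_of[leaf]
            parent.children[parent.children.index(leaf)] = clade
    return out, registry


def _assign_supports(tree: LabeledTree, model: tuple, rng: np.random.Generator) -> None:
    for node in tree.internal_nodes():
        if node is tree.root:
            continue
        if model[0] == "fixed":
            node.support = float(model[1])
        elif model[0] == "uniform":
            node.support = float(rng.uniform(model[1], model[2]))
        else:
            raise PhaselinkError(f"unknown support model {model!r}")


def perturb_tree(
    tree: LabeledTree, config: SimConfig, seed: Optional[int] = None
) -> LabeledTree:
    """Topological and branch-length noise.

    Applies ``config.n_nni`` random nearest-neighbor interchanges (each
    changes at most one clade in each direction), multiplies every
    branch length by an independent lognormal(0, sigma) factor, and
    draws internal supports from ``config.support_model``.  With
    ``n_nni=0`` and ``sigma=0`` the topology and lengths are unchanged.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = tree.copy()
    for _ in range(config.n_nni):
        parent_of = {c: p for p in out.preorder() for c in p.children}
        candidates = [
            n
            for n in out.preorder()
            if not n.is_leaf
            and n is not out.root
            and len(parent_of[n].children) >= 2
        ]
        if not candidates:
            break
        v = candidates[int(rng.integers(len(candidates)))]
        p = parent_of[v]
        siblings = [c for c in p.children if c is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        p.children[p.children.index(s)] = c
        v.children[v.children.index(c)] = s
    if config.length_jitter_sigma > 0:
        for node in out.preorder():
            if node.length is not None:
                node.length = float(
                    node.length * rng.lognormal(0.0, config.length_jitter_sigma)
                )
    _assign_supports(out, config.support_model, rng)
    return out


def make_paired_instance(config: SimConfig) -> SyntheticPair:
    """Build one (tree A, tree B, truth) instance.

    One Yule accession tree is expanded twice with a shared allelic
    history; a seeded subset of the non-coalescent two-allele
    accessions has its labels 0/1 swapped in tree B (the planted
    truth); tree B then receives NNI and length noise.  Deterministic
    per ``config.seed``.
    """
    seeds = _child_seeds(config.seed, 6)
    base = simulate_accession_tree(config.n_accessions, seeds[0])
    rng = np.random.default_rng(seeds[1])
    ks = sorted(config.allele_count_distribution)
    ps = [config.allele_count_distribution[k] for k in ks]
    counts = {
        leaf.allele.accession: int(rng.choice(ks, p=ps)) for leaf in base.leaves()
    }
    noncoalescent = {
        acc
        for acc, k in sorted(counts.items())
        if k == 2 and rng.random() < config.noncoalescent_fraction
    }
    tree_a, registry = expand_alleles(
        base, config, "A", seed=seeds[2], counts=counts, noncoalescent=noncoalescent
    )
    tree_b, _ = expand_alleles(
        base, config, "B", seed=seeds[3], counts=counts, noncoalescent=noncoalescent
    )

    swap_rng = np.random.default_rng(seeds[4])
    swapped: set[str] = set()
    truth: dict[str, Pairing] = {}
    for acc in sorted(registry):
        codes = registry[acc]
        if (
            acc in noncoalescent
            and len(codes) == 2
            and swap_rng.random() < config.planted_swap_fraction
        ):
            swapped.add(acc)
            truth[acc] = Pairing(acc, (("0", "1"), ("1", "0")), a_is_domain=True)
        else:
            truth[acc] = Pairing(
                acc, tuple((c, c) for c in sorted(codes)), a_is_domain=True
            )
    for leaf in tree_b.leaves():
        if leaf.allele.accession in swapped:
            flipped = {"0": "1", "1": "0"}[leaf.allele.allele_code]
            leaf.allele = AlleleLabel(leaf.allele.accession, flipped)

    tree_b = perturb_tree(tree_b, config, seed=seeds[5])
    _assign_supports(tree_a, config.support_model, np.random.default_rng(seeds[5] ^ 0x5A5A5A))
    return SyntheticPair(
        tree_a=tree_a,
        tree_b=tree_b,
        truth=truth,
        noise={
            "n_nni": config.n_nni,
            "length_jitter_sigma": config.length_jitter_sigma,
            "swapped": sorted(swapped),
            "noncoalescent": sorted(noncoalescent),
            "counts": dict(sorted(counts.items())),
            "seed": config.seed,
        },
    )
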