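"""Reduce two allele trees to comparable form.

Before two gene trees over phased alleles can be compared, they must be
pruned to the accessions they have in common, and clades made up
exclusively of alleles from one accession ("coalescent allele groups")
must be collapsed to a single branch — such groups carry no information
for choosing an allele correspondence, and removing them shrinks the
combinatorial search space.

``harmonize_leaf_sets`` then rewrites the leaves of both trees under a
chosen allele combination so the two trees share one canonical leaf-label
set, the precondition of any Robinson–Foulds computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import pandas as pd

from .errors import MappingError, NoOverlapError, PhaselinkError
from .tree_io import AlleleLabel, LabeledTree, Node

if TYPE_CHECKING:  # pragma: no cover
    from .matcher import Combination

__all__ = [
    "CollapseReport",
    "CollapsedGroup",
    "shared_accessions",
    "prune_to_accessions",
    "collapse_monoaccession_clades",
    "harmonize_leaf_sets",
]


@dataclass(frozen=True)
class CollapsedGroup:
    """One mono-accession clade reduced to a single branch."""

    accession: str
    group_code: str          # synthetic allele code "g<i>" of the new leaf
    members: tuple[str, ...]  # allele codes, by attachment depth then lexicographic
    representative: str       # the most basal member allele code
    length: Optional[float]   # stem + most-basal-member branch length


@dataclass
class CollapseReport:
    """Bookkeeping for collapsed mono-accession clades of one tree."""

    groups: list[CollapsedGroup] = field(default_factory=list)

    def members_of(self, accession: str, code: str) -> Optional[CollapsedGroup]:
        for g in self.groups:
            if g.accession == accession and g.group_code == code:
                return g
        return None

    def to_frame(self, tree_name: str = "") -> pd.DataFrame:
        rows = [
            {
                "tree": tree_name,
                "accession": g.accession,
                "group": g.group_code,
                "members": ",".join(g.members),
                "representative": g.representative,
                "length": g.length,
            }
            for g in self.groups
        ]
        return pd.DataFrame(
            rows,
            columns=["tree", "accession", "group", "members", "representative", "length"],
        )


def shared_accessions(tree_a: LabeledTree, tree_b: LabeledTree) -> set[str]:
    """Accessions present in both trees; raises if the intersection is empty."""
    common = tree_a.accessions() & tree_b.accessions()
    if not common:
        raise NoOverlapError("the two trees share no accession; matching is undefined")
    return common


def _suppress_unifurcations(root: Node) -> Node:
    """Splice out degree-2 nodes, summing branch lengths.

    The support of a spliced node is discarded — it annotated a clade
    that no longer exists.  A unifurcate root is replaced by its child.
    """

    def rec(node: Node) -> Node:
        node.children = [rec(c) for c in node.children]
        if len(node.children) == 1:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        return node

    return rec(root)


def prune_to_accessions(tree: LabeledTree, keep: set[str]) -> LabeledTree:
    """Remove all leaves whose accession is not in ``keep``.

    Degree-2 nodes arising from the removal are suppressed with their
    incident branch lengths summed; the root is retained.
    """
    if not keep:
        raise PhaselinkError("the set of accessions to keep is empty")
    out = tree.copy()

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node.allele.accession in keep else None
        node.children = [c for c in (rec(c) for c in node.children) if c is not None]
        return node if node.children else None

    root = rec(out.root)
    if root is None:
        raise PhaselinkError("pruning removed every leaf")
    return LabeledTree(_suppress_unifurcations(root))


def collapse_monoaccession_clades(
    tree: LabeledTree,
) -> tuple[LabeledTree, CollapseReport]:
    """Collapse every maximal clade whose leaves all share one accession.

    The collapsed clade is replaced by a single leaf carrying the
    accession and a synthetic allele code ``g<i>``.  Its branch length
    is the clade's stem branch plus the branch of the most basal member
    allele — the leaf attached topologically closest to the clade root,
    ties broken lexicographically by allele code.  Single leaves are
    untouched (only groups of two or more sister alleles collapse), and
    a tree with no mono-accession clade is returned unchanged with an
    empty report.
    """
    out = tree.copy()
    report = CollapseReport()
    counter = [0]

    def accessions_below(node: Node) -> set[str]:
        if node.is_leaf:
            return {node.allele.accession}
        return set().union(*(accessions_below(c) for c in node.children))

    def collapse(node: Node) -> Node:
        accession = next(iter(accessions_below(node)))
        members: list[tuple[int, str]] = []  # (depth from clade root, code)

        def walk(n: Node, depth: int) -> None:
            if n.is_leaf:
                members.append((depth, n.allele.allele_code))
            else:
                for c in n.children:
                    walk(c, depth + 1)

        walk(node, 0)
        members.sort()
        basal_depth, basal_code = members[0]
        basal_length = next(
            leaf.length
            for leaf in LabeledTree(node).leaves()
            if leaf.allele.allele_code == basal_code
        )
        if node.length is None and basal_length is None:
            length = None
        else:
            length = (node.length or 0.0) + (basal_length or 0.0)
        counter[0] += 1
        code = f"g{counter[0]}"
        report.groups.append(
            CollapsedGroup(
                accession=accession,
                group_code=code,
                members=tuple(code for _, code in members),
                representative=basal_code,
                length=length,
            )
        )
        return Node(length=length, allele=AlleleLabel(accession, code))

    def rec(node: Node) -> Node:
        if node.is_leaf:
            return node
        if len(accessions_below(node)) == 1:
            return collapse(node)
        node.children = [rec(c) for c in node.children]
        return node

    return LabeledTree(rec(out.root)), report


def _canonical_pairs(
    pairing: "object", codes_a: list[str], codes_b: list[str], duplicate: bool
) -> list[tuple[str, str]]:
    """Expand one Pairing into explicit (allele_a, allele_b) matches.

    In duplicate mode every larger-side allele must appear: unmatched
    larger-side alleles are assigned round-robin to the sorted
    smaller-side alleles (so a single allele facing two variants is
    matched to both, the concatenation rule for unbalanced accessions).
    """
    pairs = sorted(pairing.ab_pairs())
    if duplicate:
        if pairing.a_is_domain:
            larger, matched = codes_b, {b for _, b in pairs}
            domain_sorted = sorted(a for a, _ in pairs)
        else:
            larger, matched = codes_a, {a for a, _ in pairs}
            domain_sorted = sorted(b for _, b in pairs)
        unmatched = sorted(c for c in larger if c not in matched)
        for k, code in enumerate(unmatched):
            dom = domain_sorted[k % len(domain_sorted)]
            pairs.append((dom, code) if pairing.a_is_domain else (code, dom))
        pairs.sort()
    return pairs


def harmonize_leaf_sets(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    combination: "Combination",
    mode: str = "prune",
) -> tuple[LabeledTree, LabeledTree]:
    """Relabel both trees under ``combination`` to one shared leaf set.

    Each matched pair of leaves receives a canonical label
    ``accession#k``.  Unmatched alleles of unbalanced accessions are
    either removed (``mode="prune"``, with degree-2 suppression) or, in
    ``mode="duplicate"``, the smaller side's allele matched to m
    partners is replaced by m leaves on a zero-length cherry at its
    position.  On return both trees carry identical leaf-label sets.
    The inputs are not modified.
    """
    if mode not in ("prune", "duplicate"):
        raise ValueError(f"unknown harmonization mode {mode!r}")
    alleles_a = tree_a.alleles_by_accession()
    alleles_b = tree_b.alleles_by_accession()
    if set(alleles_a) != set(combination.accessions()) or set(alleles_b) != set(
        combination.accessions()
    ):
        missing = (set(alleles_a) | set(alleles_b)) ^ set(combination.accessions())
        raise MappingError(
            f"combination does not cover exactly the trees' accessions: {sorted(missing)}"
        )

    # canonical label of each (tree, accession, allele code); None => prune
    relabel_a: dict[tuple[str, str], list[AlleleLabel]] = {}
    relabel_b: dict[tuple[str, str], list[AlleleLabel]] = {}
    for pairing in combination.pairings:
        acc = pairing.accession
        codes_a, codes_b = alleles_a[acc], alleles_b[acc]
        for a_code, b_code in pairing.ab_pairs():
            if a_code not in codes_a or b_code not in codes_b:
                raise MappingError(
                    f"pairing for {acc!r} references unknown allele "
                    f"({a_code!r} / {b_code!r})"
                )
        pairs = _canonical_pairs(pairing, codes_a, codes_b, mode == "duplicate")
        for k, (a_code, b_code) in enumerate(pairs, start=1):
            canon = AlleleLabel(acc, f"#{k}")
            relabel_a.setdefault((acc, a_code), []).append(canon)
            relabel_b.setdefault((acc, b_code), []).append(canon)

    def rewrite(tree: LabeledTree, relabel: dict) -> LabeledTree:
        out = tree.copy()

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf:
                key = (node.allele.accession, node.allele.allele_code)
                canons = relabel.get(key)
                if not canons:
                    return None  # unmatched allele, prune mode
                if len(canons) == 1:
                    node.allele = canons[0]
                    return node
                # duplicate mode: m partners => zero-length cherry of m leaves
                cherry = Node(length=node.length)
                cherry.children = [
                    Node(length=0.0, allele=c) for c in sorted(canons)
                ]
                return cherry
            node.children = [
                c for c in (rec(c) for c in node.children) if c is not None
            ]
            return node if node.children else None

        root = rec(out.root)
        if root is None:
            raise MappingError("harmonization removed every leaf")
        return LabeledTree(_suppress_unifurcations(root))

    out_a = rewrite(tree_a, relabel_a)
    out_b = rewrite(tree_b, relabel_b)
    assert out_a.leaf_labels() == out_b.leaf_labels()
    return out_a, out_b
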