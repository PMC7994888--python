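"""Newick I/O and allele-labeled rooted trees.

Leaves of the trees handled here encode *accession* (the sampled
individual) plus an *allele code* describing which phased sequence
variant of a multi-copy marker the leaf represents.  The canonical
codes follow the two-round phasing scheme used for rDNA markers:

======  =======================================================
code    meaning
======  =======================================================
``s``   "single" -- only one variant recovered
``0``   first main variant (one phasing round)
``1``   second main variant
``0.0`` sub-variant of 0 from a second phasing round
``0.1`` sub-variant of 0
``1.0`` sub-variant of 1
``1.1`` sub-variant of 1
``d``   direct (unphased Sanger) sequence; default when a leaf
        label carries no delimiter
``c<k>``  clone number k
``g<i>``  synthetic code for a collapsed mono-accession group
======  =======================================================

Arbitrary free-text codes are also accepted.  Parsing is backed by
dendropy; internal-node supports are read either from node labels
(IQ-TREE / MrBayes consensus style) or from bracketed comments, and
values above 1 are interpreted as percentages and normalized to [0, 1].
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

from .errors import (
    DuplicateLeafError,
    LabelGrammarError,
    NewickParseError,
    SupportRangeError,
)

__all__ = [
    "AlleleLabel",
    "Node",
    "LabeledTree",
    "parse_leaf_label",
    "parse_newick",
    "write_newick",
]

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]':;,]")


@dataclass(frozen=True, order=True)
class AlleleLabel:
    """Parsed leaf identity: accession id plus allele code."""

    accession: str
    allele_code: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise LabelGrammarError("accession must be non-empty")
        if not self.allele_code:
            raise LabelGrammarError("allele code must be non-empty")

    def __str__(self) -> str:
        if self.allele_code == "d":
            return self.accession
        return f"{self.accession}|{self.allele_code}"


def parse_leaf_label(
    raw: str,
    delimiter: str = "|",
    regex: Optional[str] = None,
) -> AlleleLabel:
    """Split a raw leaf label into an :class:`AlleleLabel`.

    By default the accession and allele code are separated by the LAST
    occurrence of ``delimiter`` (accessions routinely contain ".", "-"
    and "/", so a reserved delimiter is the safe convention).  A label
    with no delimiter is treated as a direct (unphased) sequence and
    receives allele code ``"d"``.

    Alternatively ``regex`` may supply a grammar with named capture
    groups ``accession`` and ``allele``.
    """
    if not raw:
        raise LabelGrammarError("empty leaf label")
    if regex is not None:
        pattern = re.compile(regex)
        if "accession" not in pattern.groupindex or "allele" not in pattern.groupindex:
            raise LabelGrammarError(
                "label regex must define named groups 'accession' and 'allele'"
            )
        m = pattern.match(raw)
        if m is None:
            raise LabelGrammarError(f"leaf label {raw!r} does not match grammar")
        return AlleleLabel(m.group("accession"), m.group("allele"))
    if delimiter in raw:
        accession, _, code = raw.rpartition(delimiter)
        return AlleleLabel(accession, code)
    return AlleleLabel(raw, "d")


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the branch subtending this node
    (substitutions/site; ``None`` when absent), ``support`` the support
    of the clade this node roots, normalized to [0, 1] (``None`` when
    absent or for leaves/root).
    """

    __slots__ = ("children", "length", "support", "allele")

    def __init__(
        self,
        children: Optional[list["Node"]] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        allele: Optional[AlleleLabel] = None,
    ) -> None:
        self.children: list[Node] = children if children is not None else []
        self.length = length
        self.support = support
        self.allele = allele

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(
            [c.copy() for c in self.children], self.length, self.support, self.allele
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.allele})"
        return f"Node(n_children={len(self.children)})"


@dataclass
class LabeledTree:
    """Rooted tree with branch lengths, supports and allele-labeled leaves."""

    root: Node = field(default_factory=Node)

    def copy(self) -> "LabeledTree":
        return LabeledTree(self.root.copy())

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {str(n.allele) for n in self.leaves()}

    def accessions(self) -> set[str]:
        return {n.allele.accession for n in self.leaves()}

    def alleles_by_accession(self) -> dict[str, list[str]]:
        """Allele codes per accession, sorted, in stable order."""
        out: dict[str, list[str]] = {}
        for leaf in self.leaves():
            out.setdefault(leaf.allele.accession, []).append(leaf.allele.allele_code)
        return {acc: sorted(codes) for acc, codes in sorted(out.items())}

    def n_leaves(self) -> int:
        return len(self.leaves())

    def height(self) -> float:
        """Maximum root-to-leaf path length (missing lengths count as 0)."""

        def rec(node: Node, acc: float) -> float:
            acc += node.length or 0.0
            if node.is_leaf:
                return acc
            return max(rec(c, acc) for c in node.children)

        return max(rec(c, 0.0) for c in self.root.children) if self.root.children else 0.0

    def validate(self) -> None:
        """Check the tree invariants, raising on violation."""
        seen: set[AlleleLabel] = set()
        for node in self.preorder():
            if node.is_leaf:
                if node.allele is None:
                    raise NewickParseError("leaf without allele label")
                if node.allele in seen:
                    raise DuplicateLeafError(f"duplicate leaf label {node.allele}")
                seen.add(node.allele)
            if node.length is not None and node.length < 0:
                raise NewickParseError(f"negative branch length {node.length}")
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise SupportRangeError(f"support {node.support} outside [0, 1]")


def _support_from_dendropy(nd: dendropy.Node, convention: str) -> Optional[float]:
    label_val: Optional[float] = None
    if nd.label is not None:
        try:
            label_val = float(nd.label)
        except ValueError:
            label_val = None
    comment_val: Optional[float] = None
    for comment in nd.comments:
        try:
            comment_val = float(comment.strip("&"))
            break
        except ValueError:
            continue
    if convention == "node-label":
        return label_val
    if convention == "comment":
        return comment_val
    return label_val if label_val is not None else comment_val


def normalize_supports(tree: LabeledTree) -> LabeledTree:
    """Normalize supports to [0, 1] in place; idempotent.

    Any support above 1 anywhere marks the whole tree as using the
    percentage scale, and every support is divided by 100.  Mixed
    scales within one tree are almost certainly an input error and
    trigger a warning.
    """
    supports = [n.support for n in tree.preorder() if n.support is not None]
    for s in supports:
        if s < 0 or s > 100:
            raise SupportRangeError(f"support value {s} outside [0, 100]")
    if any(s > 1 for s in supports):
        if any(s <= 1 and s != 0 for s in supports):
            warnings.warn(
                "tree mixes supports <= 1 with supports > 1; "
                "treating the whole tree as percentages",
                stacklevel=2,
            )
        for node in tree.preorder():
            if node.support is not None:
                node.support = node.support / 100.0
    return tree


def parse_newick(
    text: str,
    support_convention: str = "auto",
    delimiter: str = "|",
    regex: Optional[str] = None,
) -> LabeledTree:
    """Parse one Newick string into a :class:`LabeledTree`.

    Supports are read from internal-node labels and/or bracketed
    comments depending on ``support_convention`` ("node-label",
    "comment", or "auto", which prefers node labels).  Support values
    above 1 are interpreted as percentages.
    """
    if support_convention not in ("auto", "node-label", "comment"):
        raise ValueError(f"unknown support convention {support_convention!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        message = str(exc)
        if "uplicate" in message or "multiple" in message.lower():
            raise DuplicateLeafError(message) from exc
        raise NewickParseError(message) from exc

    def convert(nd: dendropy.Node) -> Node:
        if nd.is_leaf():
            raw = nd.taxon.label if nd.taxon is not None else nd.label
            if raw is None:
                raise NewickParseError("unlabeled leaf in Newick input")
            return Node(length=nd.edge.length, allele=parse_leaf_label(raw, delimiter, regex))
        node = Node(
            children=[convert(c) for c in nd.child_nodes()],
            length=nd.edge.length,
            support=_support_from_dendropy(nd, support_convention),
        )
        return node

    root = convert(dtree.seed_node)
    root.support = None  # the root is not a clade with a stem
    tree = LabeledTree(root)
    normalize_supports(tree)
    tree.validate()
    return tree


def _format_length(x: float) -> str:
    return format(x, ".12g")


def _leaf_token(allele: AlleleLabel) -> str:
    token = str(allele)
    if _NEWICK_UNSAFE.search(token):
        return "'" + token.replace("'", "''") + "'"
    return token


def write_newick(tree: LabeledTree, support_scale: str = "percent") -> str:
    """Serialize a :class:`LabeledTree` to Newick.

    ``support_scale`` is "percent" (support 0.9 written as ``90``, the
    bootstrap convention) or "unit" (written as ``0.9``).  Lengths are
    written to 12 significant digits, so parse -> write -> parse is the
    identity on topology, labels, lengths and supports.
    """
    if support_scale not in ("percent", "unit"):
        raise ValueError(f"unknown support scale {support_scale!r}")

    def fmt_support(s: float) -> str:
        return _format_length(s * 100.0 if support_scale == "percent" else s)

    def rec(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            out = _leaf_token(node.allele)
        else:
            out = "(" + ",".join(rec(c, False) for c in node.children) + ")"
            if node.support is not None and not is_root:
                out += fmt_support(node.support)
        if node.length is not None:
            out += ":" + _format_length(node.length)
        return out

    return rec(tree.root, True) + ";"
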