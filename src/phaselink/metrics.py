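"""Rooted Robinson–Foulds distances, plain and weighted.

Two objectives over rooted trees with identical leaf-label sets:

* :func:`rf_distance` — the symmetric distance: the number of
  non-trivial rooted clades present in exactly one of the two trees.
  Topology only.

* :func:`weighted_rf_distance` — each clade in the symmetric difference
  contributes ``branch length x child-node support``, measured on its
  own tree, and clades whose support falls below a threshold (default
  50%) are removed from the computation entirely.  This rewards
  agreement on long, well-supported branches and ignores poorly
  supported conflict.

Trivial clades (single leaves and the full leaf set) never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import PhaselinkError
from .tree_io import LabeledTree, Node

__all__ = [
    "MetricConfig",
    "WeightedClade",
    "clade_set",
    "rf_distance",
    "weighted_rf_distance",
]


@dataclass(frozen=True)
class MetricConfig:
    """Tunables of the weighted metric.

    support_threshold
        Clades with effective support strictly below this value are
        removed from the weighted distance ("lesser than 50%" rule;
        support exactly at the threshold is retained).
    missing_support_policy
        "retain-as-1": an unannotated clade acts as fully supported
        (so nodes created by preprocessing do not silently vanish);
        "drop": unannotated clades are excluded from the filtered set.
    missing_length_policy
        "as-0": a missing branch length contributes weight 0;
        "as-1": unit length, degenerating to support-only weighting.
    """

    support_threshold: float = 0.5
    missing_support_policy: str = "retain-as-1"
    missing_length_policy: str = "as-0"

    def __post_init__(self) -> None:
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support_threshold must lie in [0, 1]")
        if self.missing_support_policy not in ("retain-as-1", "drop"):
            raise ValueError(f"unknown missing_support_policy {self.missing_support_policy!r}")
        if self.missing_length_policy not in ("as-0", "as-1"):
            raise ValueError(f"unknown missing_length_policy {self.missing_length_policy!r}")


@dataclass(frozen=True)
class WeightedClade:
    """A non-trivial rooted clade with its stem length and support."""

    leafset: frozenset[str]
    branch_length: Optional[float]
    support: Optional[float]

    def effective_support(self, config: MetricConfig) -> Optional[float]:
        if self.support is not None:
            return self.support
        return 1.0 if config.missing_support_policy == "retain-as-1" else None

    def effective_length(self, config: MetricConfig) -> float:
        if self.branch_length is not None:
            return self.branch_length
        return 0.0 if config.missing_length_policy == "as-0" else 1.0

    def weight(self, config: MetricConfig) -> float:
        support = self.effective_support(config)
        return self.effective_length(config) * (1.0 if support is None else support)


def _leaf_key(node: Node) -> str:
    return str(node.allele)


def _clade_map(
    tree: LabeledTree, config: MetricConfig, filtered: bool
) -> dict[frozenset[str], WeightedClade]:
    n_total = tree.n_leaves()
    clades: dict[frozenset[str], WeightedClade] = {}

    def rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([_leaf_key(node)])
        leafset = frozenset().union(*(rec(c) for c in node.children))
        if node is not tree.root and 2 <= len(leafset) < n_total:
            clade = WeightedClade(leafset, node.length, node.support)
            if filtered:
                support = clade.effective_support(config)
                if support is None or support < config.support_threshold:
                    return leafset
            clades[leafset] = clade
        return leafset

    rec(tree.root)
    return clades


def clade_set(
    tree: LabeledTree, config: MetricConfig = MetricConfig(), filtered: bool = False
) -> set[WeightedClade]:
    """All non-trivial rooted clades of ``tree`` with length and support.

    With ``filtered=True``, clades whose effective support falls below
    ``config.support_threshold`` are excluded.
    """
    return set(_clade_map(tree, config, filtered).values())


def _require_equal_leaves(tree_a: LabeledTree, tree_b: LabeledTree) -> None:
    la, lb = tree_a.leaf_labels(), tree_b.leaf_labels()
    if la != lb:
        diff = sorted(la ^ lb)
        raise PhaselinkError(
            f"trees have different leaf sets; symmetric difference: {diff}"
        )


def rf_distance(tree_a: LabeledTree, tree_b: LabeledTree) -> int:
    """Plain rooted Robinson–Foulds (symmetric) distance.

    The cardinality of the symmetric difference of the two trees'
    non-trivial rooted clade sets; branch lengths and supports play no
    role.
    """
    _require_equal_leaves(tree_a, tree_b)
    config = MetricConfig()
    ca = set(_clade_map(tree_a, config, filtered=False))
    cb = set(_clade_map(tree_b, config, filtered=False))
    return len(ca ^ cb)


def weighted_rf_distance(
    tree_a: LabeledTree, tree_b: LabeledTree, config: MetricConfig = MetricConfig()
) -> float:
    """Branch-length x support weighted rooted Robinson–Foulds distance.

    Each clade of the topological symmetric difference contributes the
    weight measured on its own tree — by definition it is absent from
    the other tree.  A clade whose support falls below the threshold is
    removed from the calculation entirely, so the distance is zero on
    topologically identical trees and non-increasing in the threshold.
    """
    _require_equal_leaves(tree_a, tree_b)
    ca = _clade_map(tree_a, config, filtered=False)
    cb = _clade_map(tree_b, config, filtered=False)

    def passes(clade: WeightedClade) -> bool:
        support = clade.effective_support(config)
        return support is not None and support >= config.support_threshold

    total = 0.0
    for leafset, clade in ca.items():
        if leafset not in cb and passes(clade):
            total += clade.weight(config)
    for leafset, clade in cb.items():
        if leafset not in ca and passes(clade):
            total += clade.weight(config)
    return total
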