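"""Search for the allele combination that makes two gene trees most alike.

Phased alleles of a multi-copy marker cannot always be linked across
two loci (e.g. ITS and ETS of the 45S rDNA cistron) from sequence data
alone.  This module recovers the per-accession allele correspondence by
optimization: the objective of a candidate combination is the distance
between the two trees after relabeling the leaves to that combination,
and the best combination is the one producing the most similar trees.

The search runs in two phases:

1. **Local phase** (plain, topology-only Robinson–Foulds): starting
   from a random combination, each focal accession's pairings are
   evaluated in turn with the other accessions held fixed; all
   minimizers are retained.  Repeated over seeded restarts, this
   prunes the exponential space down to per-accession candidate sets.
2. **Global phase** (weighted rooted Robinson–Foulds with the <50%
   support-removal rule): the Cartesian product of the retained sets
   is scanned exhaustively; all global minima are reported, with a
   per-accession verdict of ``keep``, ``swap``, or ``equivocal``.

Because the identity pairing is always force-included in every retained
set, the reported optimum can never be worse than not swapping at all.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional

import pandas as pd

from .errors import CapacityError, PhaselinkError
from .metrics import MetricConfig, rf_distance, weighted_rf_distance
from .preprocess import (
    CollapseReport,
    collapse_monoaccession_clades,
    harmonize_leaf_sets,
    prune_to_accessions,
    shared_accessions,
)
from .tree_io import LabeledTree

__all__ = [
    "Pairing",
    "Combination",
    "SearchConfig",
    "MatchResult",
    "enumerate_pairings",
    "identity_pairing",
    "apply_combination",
    "local_optimize",
    "global_optimize",
    "exhaustive_search",
    "link_alleles",
    "concatenation_plan",
]

SCORE_TOL = 1e-9  # absolute tolerance for floating-point score ties


@dataclass(frozen=True, order=True)
class Pairing:
    """Injective allele map for one accession.

    ``mapping`` maps the smaller of the two allele-code sets (the
    domain) into the larger; ``a_is_domain`` records whether the domain
    lives in tree A.  Alleles collapsed into one group count as a
    single allele code.
    """

    accession: str
    mapping: tuple[tuple[str, str], ...]  # (domain code, image code), sorted
    a_is_domain: bool = True

    def domain_codes(self) -> set[str]:
        return {d for d, _ in self.mapping}

    def image_codes(self) -> set[str]:
        return {i for _, i in self.mapping}

    def ab_pairs(self) -> tuple[tuple[str, str], ...]:
        """Matches as (allele in tree A, allele in tree B) pairs."""
        if self.a_is_domain:
            return self.mapping
        return tuple(sorted((b, a) for a, b in self.mapping))



@dataclass(frozen=True, order=True)
class Combination:
    """One Pairing per shared accession."""

    pairings: tuple[Pairing, ...]  # sorted by accession

    def __post_init__(self) -> None:
        accs = [p.accession for p in self.pairings]
        if len(set(accs)) != len(accs):
            raise PhaselinkError("combination holds two pairings for one accession")
        object.__setattr__(self, "pairings", tuple(sorted(self.pairings)))

    def accessions(self) -> list[str]:
        return [p.accession for p in self.pairings]

    def pairing_for(self, accession: str) -> Pairing:
        for p in self.pairings:
            if p.accession == accession:
                return p
        raise KeyError(accession)

    def with_pairing(self, pairing: Pairing) -> "Combination":
        rest = tuple(p for p in self.pairings if p.accession != pairing.accession)
        return Combination(rest + (pairing,))

    def to_dict(self) -> dict:
        return {
            p.accession: {"pairs": [list(ab) for ab in p.ab_pairs()]}
            for p in self.pairings
        }


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the two-phase search."""

    seed: int = 0
    restarts: int = 10
    max_sweeps: int = 20
    global_cap: int = 10**6
    mode: str = "prune"  # harmonization of unbalanced accessions
    metric: MetricConfig = field(default_factory=MetricConfig)

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.max_sweeps < 1 or self.global_cap < 1:
            raise ValueError("restarts, max_sweeps and global_cap must be positive")


@dataclass
class MatchResult:
    """Outcome of the two-phase search."""

    optima: list[Combination]
    score: float
    verdicts: dict[str, str]  # accession -> keep | swap | equivocal
    retained_sizes: dict[str, int]
    stats: dict
    alleles_a: Optional[dict[str, list[str]]] = None
    alleles_b: Optional[dict[str, list[str]]] = None

    @property
    def best(self) -> Combination:
        return self.optima[0]

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "n_optima": len(self.optima),
            "optima": [c.to_dict() for c in self.optima],
            "verdicts": dict(sorted(self.verdicts.items())),
            "retained_sizes": dict(sorted(self.retained_sizes.items())),
            "stats": self.stats,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def verdict_frame(self) -> pd.DataFrame:
        rows = []
        for pairing in self.best.pairings:
            rows.append(
                {
                    "accession": pairing.accession,
                    "verdict": self.verdicts[pairing.accession],
                    "best_pairing": ";".join(
                        f"{a}={b}" for a, b in pairing.ab_pairs()
                    ),
                    "n_optima": len(
                        {c.pairing_for(pairing.accession) for c in self.optima}
                    ),
                }
            )
        return pd.DataFrame(rows, columns=["accession", "verdict", "best_pairing", "n_optima"])


def enumerate_pairings(
    accession: str, alleles_a: Iterable[str], alleles_b: Iterable[str]
) -> list[Pairing]:
    """All injective maps from the smaller allele set into the larger.

    Deterministic lexicographic order; the first element is always the
    canonical identity pairing.  Count = |larger|! / (|larger|-|smaller|)!.
    """
    codes_a, codes_b = sorted(set(alleles_a)), sorted(set(alleles_b))
    if not codes_a or not codes_b:
        raise PhaselinkError(f"accession {accession!r} has an empty allele set")
    a_is_domain = len(codes_a) <= len(codes_b)
    domain, codomain = (codes_a, codes_b) if a_is_domain else (codes_b, codes_a)
    out = []
    for images in itertools.permutations(codomain, len(domain)):
        mapping = tuple(zip(domain, images))
        out.append(Pairing(accession, mapping, a_is_domain))
    return out


def identity_pairing(
    accession: str, alleles_a: Iterable[str], alleles_b: Iterable[str]
) -> Pairing:
    """The canonical no-swap pairing (sorted codes aligned element-wise)."""
    codes_a, codes_b = sorted(set(alleles_a)), sorted(set(alleles_b))
    a_is_domain = len(codes_a) <= len(codes_b)
    domain, codomain = (codes_a, codes_b) if a_is_domain else (codes_b, codes_a)
    return Pairing(accession, tuple(zip(domain, codomain)), a_is_domain)


def apply_combination(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    combination: Combination,
    mode: str = "prune",
) -> tuple[LabeledTree, LabeledTree]:
    """Relabel both trees under ``combination``; pure, inputs untouched."""
    return harmonize_leaf_sets(tree_a, tree_b, combination, mode)


def _score(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    combination: Combination,
    mode: str,
    metric: Callable[[LabeledTree, LabeledTree], float],
) -> float:
    ha, hb = harmonize_leaf_sets(tree_a, tree_b, combination, mode)
    return metric(ha, hb)


def _pairing_space(
    tree_a: LabeledTree, tree_b: LabeledTree
) -> dict[str, list[Pairing]]:
    alleles_a = tree_a.alleles_by_accession()
    alleles_b = tree_b.alleles_by_accession()
    common = sorted(set(alleles_a) & set(alleles_b))
    return {
        acc: enumerate_pairings(acc, alleles_a[acc], alleles_b[acc]) for acc in common
    }


def local_optimize(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    config: SearchConfig = SearchConfig(),
) -> dict[str, list[Pairing]]:
    """Local phase: retain per-accession pairings under plain RF.

    For each seeded restart, alleles are first assigned at random for
    every accession; then each focal accession's pairings are all
    evaluated with the non-focal assignment held fixed, and every
    minimizer is recorded.  Sweeps repeat to a fixed point (capped at
    ``max_sweeps``); minimizer sets are unioned over restarts and the
    identity pairing is always included.  Accessions whose alleles
    fully collapsed (one code on each side) contribute their single
    trivial pairing without being enumerated.
    """
    space = _pairing_space(tree_a, tree_b)
    retained: dict[str, set[Pairing]] = {acc: set() for acc in space}
    active = [acc for acc, ps in space.items() if len(ps) > 1]
    for acc, pairings in space.items():
        if len(pairings) == 1:
            retained[acc].add(pairings[0])

    if active:
        for r in range(config.restarts):
            rng = random.Random(config.seed + 7919 * r)
            current = Combination(
                tuple(rng.choice(space[acc]) for acc in space)
            )
            order = list(active)
            rng.shuffle(order)
            for _ in range(config.max_sweeps):
                changed = False
                for focal in order:
                    best_score: Optional[int] = None
                    minimizers: list[Pairing] = []
                    for pairing in space[focal]:
                        cand = current.with_pairing(pairing)
                        s = _score(tree_a, tree_b, cand, config.mode, rf_distance)
                        if best_score is None or s < best_score:
                            best_score, minimizers = s, [pairing]
                        elif s == best_score:
                            minimizers.append(pairing)
                    retained[focal].update(minimizers)
                    if current.pairing_for(focal) not in minimizers:
                        current = current.with_pairing(minimizers[0])
                        changed = True
                if not changed:
                    break

    for acc in space:  # "keep" must always be expressible
        retained[acc].add(space[acc][0])
    # deterministic order: enumeration order of the full pairing list
    return {
        acc: [p for p in space[acc] if p in retained[acc]] for acc in sorted(space)
    }


def _scan(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    candidate_sets: dict[str, list[Pairing]],
    config: SearchConfig,
) -> tuple[list[Combination], float, int]:
    """Exhaustively score the Cartesian product of the candidate sets."""
    total = 1
    for ps in candidate_sets.values():
        total *= len(ps)
    if total > config.global_cap:
        raise CapacityError(
            f"{total} combinations exceed the cap of {config.global_cap}; "
            "tighten the local phase or restrict accessions"
        )
    metric = lambda a, b: weighted_rf_distance(a, b, config.metric)
    accs = sorted(candidate_sets)
    best: Optional[float] = None
    optima: list[tuple[float, Combination]] = []
    n_evaluated = 0
    for choice in itertools.product(*(candidate_sets[acc] for acc in accs)):
        combination = Combination(tuple(choice))
        s = _score(tree_a, tree_b, combination, config.mode, metric)
        n_evaluated += 1
        if best is None:
            best = s
            optima = [(s, combination)]
        elif s < best - SCORE_TOL:
            best = s
            optima = [(x, c) for x, c in optima if x <= best + SCORE_TOL]
            optima.append((s, combination))
        elif s <= best + SCORE_TOL:
            best = min(best, s)
            optima.append((s, combination))
    assert best is not None
    kept = sorted(c for x, c in optima if x <= best + SCORE_TOL)
    return kept, best, n_evaluated


def _verdicts(
    optima: list[Combination], identities: dict[str, Pairing]
) -> dict[str, str]:
    """keep/swap/equivocal per accession over the full optimum set.

    Two or more distinct optimal pairings => equivocal; otherwise keep
    when the unique pairing is the canonical identity, else swap.
    """
    verdicts: dict[str, str] = {}
    for pairing in optima[0].pairings:
        acc = pairing.accession
        distinct = {c.pairing_for(acc) for c in optima}
        if len(distinct) > 1:
            verdicts[acc] = "equivocal"
        else:
            verdicts[acc] = "keep" if next(iter(distinct)) == identities[acc] else "swap"
    return verdicts


def _attach_context(
    result: MatchResult, tree_a: LabeledTree, tree_b: LabeledTree
) -> MatchResult:
    result.alleles_a = tree_a.alleles_by_accession()
    result.alleles_b = tree_b.alleles_by_accession()
    return result


def global_optimize(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    retained: dict[str, list[Pairing]],
    config: SearchConfig = SearchConfig(),
) -> MatchResult:
    """Global phase: exhaustive scan of the retained Cartesian product.

    Scores every combination under the weighted rooted RF metric and
    returns all global minima (ties at 1e-9), with per-accession
    verdicts: a single optimal pairing gives ``keep`` (identity) or
    ``swap`` (non-identity); two or more distinct pairings among the
    optima give ``equivocal``.
    """
    for acc, ps in retained.items():
        if not ps:
            raise PhaselinkError(f"empty retained set for accession {acc!r}")
    alleles_a = tree_a.alleles_by_accession()
    alleles_b = tree_b.alleles_by_accession()
    identities = {
        acc: identity_pairing(acc, alleles_a[acc], alleles_b[acc]) for acc in retained
    }
    optima, best, n_evaluated = _scan(tree_a, tree_b, retained, config)
    result = MatchResult(
        optima=optima,
        score=best,
        verdicts=_verdicts(optima, identities),
        retained_sizes={acc: len(ps) for acc, ps in retained.items()},
        stats={
            "combinations_evaluated": n_evaluated,
            "restarts": config.restarts,
            "seed": config.seed,
        },
    )
    return _attach_context(result, tree_a, tree_b)


def exhaustive_search(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    config: SearchConfig = SearchConfig(),
    preprocessed: bool = False,
) -> MatchResult:
    """Brute force over ALL combinations, skipping the local phase.

    Exact but exponential; intended for small instances and as the
    reference the heuristic pipeline is validated against.
    """
    if not preprocessed:
        tree_a, tree_b, _, _ = preprocess_pair(tree_a, tree_b)
    space = _pairing_space(tree_a, tree_b)
    alleles_a = tree_a.alleles_by_accession()
    alleles_b = tree_b.alleles_by_accession()
    identities = {
        acc: identity_pairing(acc, alleles_a[acc], alleles_b[acc]) for acc in space
    }
    optima, best, n_evaluated = _scan(tree_a, tree_b, space, config)
    result = MatchResult(
        optima=optima,
        score=best,
        verdicts=_verdicts(optima, identities),
        retained_sizes={acc: len(ps) for acc, ps in space.items()},
        stats={"combinations_evaluated": n_evaluated, "restarts": 0, "seed": config.seed},
    )
    return _attach_context(result, tree_a, tree_b)


def preprocess_pair(
    tree_a: LabeledTree, tree_b: LabeledTree
) -> tuple[LabeledTree, LabeledTree, CollapseReport, CollapseReport]:
    """Prune both trees to shared accessions and collapse allele groups."""
    common = shared_accessions(tree_a, tree_b)
    ta = prune_to_accessions(tree_a, common)
    tb = prune_to_accessions(tree_b, common)
    ta, report_a = collapse_monoaccession_clades(ta)
    tb, report_b = collapse_monoaccession_clades(tb)
    return ta, tb, report_a, report_b


def link_alleles(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    config: SearchConfig = SearchConfig(),
) -> MatchResult:
    """Full pipeline: prune, collapse, local phase, global phase.

    Deterministic given identical inputs, seed and configuration.  The
    returned result additionally carries the two collapse reports in
    ``stats`` metadata-adjacent attributes ``collapse_a``/``collapse_b``
    for downstream expansion.
    """
    ta, tb, report_a, report_b = preprocess_pair(tree_a, tree_b)
    retained = local_optimize(ta, tb, config)
    result = global_optimize(ta, tb, retained, config)
    result.stats["n_shared_accessions"] = len(ta.accessions())
    result.collapse_a = report_a  # type: ignore[attr-defined]
    result.collapse_b = report_b  # type: ignore[attr-defined]
    return result


def concatenation_plan(
    result: MatchResult,
    collapse_a: Optional[CollapseReport] = None,
    collapse_b: Optional[CollapseReport] = None,
) -> pd.DataFrame:
    """Tabulate which marker-A allele is concatenated with which of B.

    Uses the first optimal combination in deterministic order
    (equivocal accessions are flagged).  An allele of the smaller side
    matched to m partners appears in m rows — a single sequence facing
    two variants of the other region is concatenated with both.
    Collapsed groups are expanded back to their representative allele
    code with the member alleles listed.
    """
    collapse_a = collapse_a if collapse_a is not None else getattr(result, "collapse_a", None)
    collapse_b = collapse_b if collapse_b is not None else getattr(result, "collapse_b", None)
    from .preprocess import _canonical_pairs

    rows = []
    for pairing in result.best.pairings:
        acc = pairing.accession
        # the full allele sets (needed to expand unmatched alleles) come
        # from the search context; fall back to the pairing's own codes
        if result.alleles_a is not None and acc in result.alleles_a:
            a_codes = list(result.alleles_a[acc])
        else:
            a_codes = sorted(
                pairing.domain_codes() if pairing.a_is_domain else pairing.image_codes()
            )
        if result.alleles_b is not None and acc in result.alleles_b:
            b_codes = list(result.alleles_b[acc])
        else:
            b_codes = sorted(
                pairing.image_codes() if pairing.a_is_domain else pairing.domain_codes()
            )
        pairs = _canonical_pairs(pairing, a_codes, b_codes, duplicate=True)
        for a_code, b_code in pairs:
            row = {
                "accession": acc,
                "allele_a": a_code,
                "allele_b": b_code,
                "members_a": "",
                "members_b": "",
                "equivocal": result.verdicts.get(acc) == "equivocal",
            }
            for side, code, report in (
                ("a", a_code, collapse_a),
                ("b", b_code, collapse_b),
            ):
                if report is not None:
                    group = report.members_of(acc, code)
                    if group is not None:
                        row[f"allele_{side}"] = group.representative
                        row[f"members_{side}"] = ",".join(group.members)
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["accession", "allele_a", "allele_b", "members_a", "members_b", "equivocal"],
    )
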