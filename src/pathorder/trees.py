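"""Reduced mutation posets and weighted sums over tree-consistent orders.

A candidate subclone tree induces a strict partial order on any subset of its
mutations: ``u`` precedes ``v`` iff the subclone carrying ``u`` is a proper
ancestor of the subclone carrying ``v``. Mutations on the same subclone are
mutually incomparable — any relative order between them is consistent with
the tree. Mutation orders consistent with a tree are exactly the linear
extensions of this poset.

For a pathway pair, candidate trees are reduced to the pair's mutations,
structurally identical reductions are merged (posteriors added), and the
merged list is truncated to the smallest high-posterior prefix. Sums over
linear extensions of position-dependent weight products are computed exactly
by dynamic programming over down-closed subsets.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .cohort import CandidateTree, PatientSample

__all__ = [
    "ReducedPoset",
    "ExtensionWeights",
    "reduce_tree",
    "merge_reduced",
    "truncate_by_cumulative",
    "enumerate_extensions",
    "extension_weighted_sum",
    "count_extensions",
    "patient_posets",
    "poset_to_dot",
]

#: Hard bound for explicit extension enumeration (oracle use only).
MAX_ENUMERATION_SIZE = 10


@dataclass(frozen=True)
class ReducedPoset:
    """Induced strict-ancestry order on a mutation subset, with posterior weight.

    ``precedes`` is transitively closed (ancestry is transitive), irreflexive
    and antisymmetric. ``elements`` is kept sorted so that structurally equal
    reductions compare equal.
    """

    elements: tuple[str, ...]
    precedes: frozenset[tuple[str, str]]
    posterior: float

    def __post_init__(self) -> None:
        if tuple(sorted(self.elements)) != self.elements:
            object.__setattr__(self, "elements", tuple(sorted(self.elements)))
        elems = set(self.elements)
        for u, v in self.precedes:
            if u == v:
                raise ValueError(f"reflexive pair ({u!r}, {v!r}) in precedes")
            if u not in elems or v not in elems:
                raise ValueError(f"precedes pair ({u!r}, {v!r}) outside elements")
        if not self.posterior > 0:
            raise ValueError("poset posterior must be > 0")

    @property
    def n(self) -> int:
        return len(self.elements)

    def canonical_key(self) -> tuple:
        """Stable identity of the structure (elements + closed order relation)."""
        return (self.elements, tuple(sorted(self.precedes)))

    def predecessor_masks(self) -> list[int]:
        """Bitmask of strict predecessors for each element (by element index)."""
        index = {e: i for i, e in enumerate(self.elements)}
        masks = [0] * len(self.elements)
        for u, v in self.precedes:
            masks[index[v]] |= 1 << index[u]
        return masks


@dataclass(frozen=True)
class ExtensionWeights:
    """Position-dependent category weights w(k, category) for extension sums.

    ``categories`` maps mutation id -> category label; ``weight`` is a
    callable of (1-based position, category label).
    """

    categories: Mapping[str, str]
    weight: Callable[[int, str], float]

    @classmethod
    def constant(cls, categories: Mapping[str, str], table: Mapping[str, float]) -> "ExtensionWeights":
        """Position-independent weights, e.g. the background distribution q."""
        return cls(categories=categories, weight=lambda k, label: table[label])

    @classmethod
    def from_rows(
        cls,
        categories: Mapping[str, str],
        rows: Sequence[Mapping[str, float]],
    ) -> "ExtensionWeights":
        """Row-per-position weights; positions beyond the last row reuse it."""
        last = len(rows) - 1
        return cls(categories=categories, weight=lambda k, label: rows[min(k - 1, last)][label])


def reduce_tree(tree: CandidateTree, keep: Iterable[str]) -> ReducedPoset:
    """Project a candidate tree onto the mutation subset ``keep``.

    (u, v) is in ``precedes`` iff u's node is a proper ancestor of v's node.
    Same-node mutations are incomparable.
    """
    keep = sorted(set(keep))
    for mid in keep:
        if mid not in tree.assignment:
            raise ValueError(f"mutation {mid!r} not assigned in tree")
    # ancestor sets per distinct node, computed once
    nodes = {tree.assignment[mid] for mid in keep}
    ancestors = {node: set(tree.ancestors(node)) for node in nodes}
    precedes = frozenset(
        (u, v)
        for u in keep
        for v in keep
        if u != v and tree.assignment[u] in ancestors[tree.assignment[v]]
    )
    return ReducedPoset(elements=tuple(keep), precedes=precedes, posterior=tree.posterior)


def merge_reduced(posets: Sequence[ReducedPoset]) -> list[ReducedPoset]:
    """Merge structurally identical posets, summing their posteriors.

    Output is sorted by canonical key; total posterior mass is conserved.
    """
    groups: dict[tuple, list[ReducedPoset]] = {}
    for p in posets:
        groups.setdefault(p.canonical_key(), []).append(p)
    merged = [
        dataclasses.replace(group[0], posterior=math.fsum(p.posterior for p in group))
        for group in groups.values()
    ]
    merged.sort(key=lambda p: p.canonical_key())
    return merged


def truncate_by_cumulative(
    posets: Sequence[ReducedPoset], threshold: float = 0.95
) -> list[ReducedPoset]:
    """Keep the shortest high-posterior prefix and renormalize it to sum to 1.

    Posets are sorted by descending posterior (ties broken by canonical key
    for reproducibility); the smallest prefix whose cumulative posterior
    reaches ``threshold`` is retained.
    """
    if not posets:
        raise ValueError("cannot truncate an empty poset list")
    ordered = sorted(posets, key=lambda p: (-p.posterior, p.canonical_key()))
    kept: list[ReducedPoset] = []
    cum = 0.0
    for p in ordered:
        kept.append(p)
        cum += p.posterior
        if cum >= threshold - 1e-12:
            break
    total = math.fsum(p.posterior for p in kept)
    return [dataclasses.replace(p, posterior=p.posterior / total) for p in kept]


def enumerate_extensions(poset: ReducedPoset) -> list[tuple[str, ...]]:
    """All linear extensions, lexicographically ordered. Oracle use only (n <= 10)."""
    if poset.n > MAX_ENUMERATION_SIZE:
        raise ValueError(f"enumeration bounded at {MAX_ENUMERATION_SIZE} elements, got {poset.n}")
    elements = poset.elements
    pred = poset.predecessor_masks()
    out: list[tuple[str, ...]] = []
    seq: list[str] = []

    def rec(mask: int) -> None:
        if len(seq) == len(elements):
            out.append(tuple(seq))
            return
        for i, e in enumerate(elements):
            bit = 1 << i
            if not mask & bit and pred[i] & ~mask == 0:
                seq.append(e)
                rec(mask | bit)
                seq.pop()

    rec(0)
    return out


def extension_weighted_sum(poset: ReducedPoset, weights: ExtensionWeights) -> float:
    """Sum over linear extensions of the positional weight product.

    Returns sum over orders (m_1, ..., m_n) consistent with the poset of
    prod_k w(k, category(m_k)), computed by dynamic programming over
    down-closed subsets (position = subset size). Exact to floating point;
    with all-ones weights this is the number of linear extensions.
    """
    n = poset.n
    if n == 0:
        return 1.0
    pred = poset.predecessor_masks()
    labels = [weights.categories[e] for e in poset.elements]
    level: dict[int, float] = {0: 1.0}
    for pos in range(1, n + 1):
        nxt: dict[int, float] = {}
        for mask, val in level.items():
            for i in range(n):
                bit = 1 << i
                if not mask & bit and pred[i] & ~mask == 0:
                    w = weights.weight(pos, labels[i])
                    if w != 0.0:
                        key = mask | bit
                        nxt[key] = nxt.get(key, 0.0) + val * w
        level = nxt
        if not level:
            return 0.0
    return level[(1 << n) - 1]


def count_extensions(poset: ReducedPoset) -> float:
    """Number of linear extensions (unit-weight DP)."""
    ones = ExtensionWeights(
        categories={e: "_" for e in poset.elements}, weight=lambda k, label: 1.0
    )
    return extension_weighted_sum(poset, ones)


def patient_posets(
    patient: PatientSample,
    keep: Iterable[str] | None = None,
    threshold: float = 0.95,
) -> list[ReducedPoset]:
    """Reduce, merge and truncate a patient's candidate trees.

    ``keep`` defaults to all of the patient's (typically pair-restricted)
    mutations. Returns truncated posets with posteriors summing to 1; a
    patient without trees yields an empty list.
    """
    if not patient.trees:
        return []
    if keep is None:
        keep = patient.mutation_ids
    reduced = [reduce_tree(t, keep) for t in patient.trees]
    return truncate_by_cumulative(merge_reduced(reduced), threshold=threshold)


def poset_to_dot(poset: ReducedPoset) -> str:
    """Debug rendering of a reduced poset as DOT (covering relations only)."""
    covers = {
        (u, v)
        for (u, v) in poset.precedes
        if not any((u, w) in poset.precedes and (w, v) in poset.precedes for w in poset.elements)
    }
    lines = ["digraph reduced_poset {"]
    for e in poset.elements:
        lines.append(f'  "{e}";')
    for u, v in sorted(covers):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
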