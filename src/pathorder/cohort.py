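"""Cohort data model, serialization and preprocessing.

A *cohort* is a list of patients. Each patient carries the non-synonymous
somatic mutations called in their tumor (with a per-mutation functional
impact score ``r`` in [0, 1], the probability that the mutation is a
functional/driver event rather than a passenger) and a set of candidate
subclone phylogenies with posterior probabilities, as produced by tumor
phylogeny reconstruction tools (PhyloWGS, Canopy, ...). Nodes of a candidate
tree are subclones; a mutation is assigned to the subclone in which it first
arose, so tree ancestry encodes within-patient temporal order.

Pathway membership comes from gene sets (GMT files). Because the ordering
model requires mutually exclusive categories, each analyzed pathway pair
(A, B) is re-organized into the disjoint categories A\\B, B\\A and A∩B before
any likelihood is computed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "A_ONLY",
    "B_ONLY",
    "AB_SHARED",
    "POSTERIOR_TOL",
    "CohortError",
    "MutationRecord",
    "CandidateTree",
    "PatientSample",
    "PathwayCatalog",
    "PairCategories",
    "read_cohort",
    "write_cohort",
    "cohort_equal",
    "read_pathway_gmt",
    "filter_hypermutators",
    "make_pair_categories",
    "restrict_patient_to_pair",
    "read_phylowgs_summary",
]

#: Category labels for a pathway pair, in canonical alphabet order.
A_ONLY = "A_only"
B_ONLY = "B_only"
AB_SHARED = "AB_shared"
CATEGORY_ORDER = (A_ONLY, B_ONLY, AB_SHARED)

#: Tree posteriors must sum to 1 within this tolerance; larger deviations are
#: treated as data corruption rather than rounding.
POSTERIOR_TOL = 1e-6


class CohortError(ValueError):
    """Schema or invariant violation in cohort data."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation: identity, gene, functional impact score.

    ``category`` is assigned only after restriction to a pathway pair and is
    one of the pair's mutually exclusive labels.
    """

    mutation_id: str
    gene: str
    functional_score: float
    category: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.functional_score <= 1.0):
            raise CohortError(
                f"functional_score {self.functional_score!r} of mutation "
                f"{self.mutation_id!r} outside [0, 1]"
            )


@dataclass
class CandidateTree:
    """A rooted subclone tree with mutation assignments and posterior weight.

    ``parent`` maps each node to its parent (``None`` for the unique root);
    ``assignment`` maps mutation ids to the node where the mutation arose.
    """

    parent: dict[str, str | None]
    assignment: dict[str, str]
    posterior: float

    def validate(self, owner: str = "?") -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise CohortError(
                f"patient {owner!r}: tree must have exactly one root, found {len(roots)}"
            )
        for node in self.parent:
            seen: set[str] = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise CohortError(f"patient {owner!r}: cycle in parent map at node {cur!r}")
                seen.add(cur)
                nxt = self.parent.get(cur, "__missing__")
                if nxt == "__missing__":
                    raise CohortError(f"patient {owner!r}: parent {cur!r} is not a node")
                cur = nxt
        for mid, node in self.assignment.items():
            if node not in self.parent:
                raise CohortError(
                    f"patient {owner!r}: mutation {mid!r} assigned to unknown node {node!r}"
                )
        if not self.posterior > 0:
            raise CohortError(f"patient {owner!r}: tree posterior must be > 0")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    def ancestors(self, node: str) -> Iterator[str]:
        """Proper ancestors of ``node``, nearest first."""
        cur = self.parent[node]
        while cur is not None:
            yield cur
            cur = self.parent[cur]

    def is_proper_ancestor(self, u: str, v: str) -> bool:
        return u != v and any(a == u for a in self.ancestors(v))


@dataclass
class PatientSample:
    """One patient's mutations plus candidate-tree posterior set."""

    patient_id: str
    mutations: list[MutationRecord]
    trees: list[CandidateTree]

    @property
    def c(self) -> int:
        """Total mutation count c_j."""
        return len(self.mutations)

    @property
    def mutation_ids(self) -> list[str]:
        return [m.mutation_id for m in self.mutations]

    def mutation_by_id(self) -> dict[str, MutationRecord]:
        return {m.mutation_id: m for m in self.mutations}

    def pathway_counts(self, catalog: "PathwayCatalog") -> dict[str, int]:
        """Per-pathway mutation counts Y_ij (a gene may count in several pathways)."""
        counts = {name: 0 for name in catalog.pathways}
        for m in self.mutations:
            for name, genes in catalog.pathways.items():
                if m.gene in genes:
                    counts[name] += 1
        return counts

    def validate(self, strict_assignment: bool = True) -> None:
        ids = self.mutation_ids
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"patient {self.patient_id!r}: duplicate mutation ids {dup}")
        for tree in self.trees:
            tree.validate(self.patient_id)
            if strict_assignment:
                missing = set(ids) - set(tree.assignment)
                extra = set(tree.assignment) - set(ids)
                if missing or extra:
                    raise CohortError(
                        f"patient {self.patient_id!r}: tree assignment mismatch "
                        f"(missing {sorted(missing)}, extra {sorted(extra)})"
                    )
        if self.trees:
            total = math.fsum(t.posterior for t in self.trees)
            if abs(total - 1.0) > POSTERIOR_TOL:
                raise CohortError(
                    f"patient {self.patient_id!r}: tree posteriors sum to {total!r}, "
                    f"deviating from 1 by more than {POSTERIOR_TOL}"
                )
            if total != 1.0:
                for t in self.trees:
                    t.posterior /= total


@dataclass(frozen=True)
class PathwayCatalog:
    """Named gene sets. Overlap between pathways is legal at catalog level."""

    pathways: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise CohortError(f"pathway {name!r} has an empty gene set")

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def names(self) -> list[str]:
        return list(self.pathways)

    def genes(self, name: str) -> frozenset[str]:
        try:
            return self.pathways[name]
        except KeyError:
            raise CohortError(f"unknown pathway {name!r}") from None


@dataclass(frozen=True)
class PairCategories:
    """Mutually exclusive gene categories for one pathway pair.

    Built as (A\\B, B\\A, A∩B) with empty categories dropped, so the labels
    partition A∪B.
    """

    pair: tuple[str, str]
    categories: dict[str, frozenset[str]]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def category_of(self, gene: str) -> str | None:
        for label, genes in self.categories.items():
            if gene in genes:
                return label
        return None


# ---------------------------------------------------------------------------
# Canonical cohort JSON
# ---------------------------------------------------------------------------


def _patient_from_dict(d: Mapping) -> PatientSample:
    pid = d.get("patient_id")
    if not isinstance(pid, str):
        raise CohortError(f"patient entry missing string 'patient_id': {d!r}")
    try:
        mutations = [
            MutationRecord(
                mutation_id=str(m["mutation_id"]),
                gene=str(m["gene"]),
                functional_score=float(m["functional_score"]),
            )
            for m in d.get("mutations", [])
        ]
        trees = []
        for t in d.get("trees", []):
            parent: dict[str, str | None] = {}
            assignment: dict[str, str] = {}
            for node in t["nodes"]:
                nid = str(node["id"])
                par = node.get("parent")
                parent[nid] = None if par is None else str(par)
                for mid in node.get("mutations", []):
                    if str(mid) in assignment:
                        raise CohortError(
                            f"patient {pid!r}: mutation {mid!r} assigned to two nodes"
                        )
                    assignment[str(mid)] = nid
            trees.append(
                CandidateTree(parent=parent, assignment=assignment, posterior=float(t["posterior"]))
            )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, CohortError):
            raise
        raise CohortError(f"patient {pid!r}: malformed entry ({exc})") from exc
    patient = PatientSample(patient_id=pid, mutations=mutations, trees=trees)
    patient.validate()
    return patient


def read_cohort(path) -> list[PatientSample]:
    """Read canonical cohort JSON, validating all invariants.

    Posteriors summing to 1 within :data:`POSTERIOR_TOL` are renormalized;
    larger deviations raise :class:`CohortError` naming the patient.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CohortError(f"malformed cohort JSON: {exc}") from exc
    if not isinstance(data, dict) or "patients" not in data:
        raise CohortError("cohort JSON must be an object with a 'patients' list")
    return [_patient_from_dict(p) for p in data["patients"]]


def _patient_to_dict(p: PatientSample) -> dict:
    trees = []
    for t in p.trees:
        by_node: dict[str, list[str]] = {n: [] for n in t.parent}
        for mid, node in t.assignment.items():
            by_node[node].append(mid)
        trees.append(
            {
                "posterior": t.posterior,
                "nodes": [
                    {"id": n, "parent": t.parent[n], "mutations": sorted(by_node[n])}
                    for n in sorted(t.parent)
                ],
            }
        )
    return {
        "patient_id": p.patient_id,
        "mutations": [
            {
                "mutation_id": m.mutation_id,
                "gene": m.gene,
                "functional_score": m.functional_score,
            }
            for m in p.mutations
        ],
        "trees": trees,
    }


def write_cohort(cohort: Iterable[PatientSample], path) -> None:
    """Write canonical cohort JSON (UTF-8, round-trips through read_cohort)."""
    payload = {"patients": [_patient_to_dict(p) for p in cohort]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def cohort_equal(a: list[PatientSample], b: list[PatientSample], rel: float = 1e-12) -> bool:
    """Structural equality of two cohorts, with float tolerance on posteriors."""
    if len(a) != len(b):
        return False
    for pa, pb in zip(a, b):
        if pa.patient_id != pb.patient_id or pa.mutations != pb.mutations:
            return False
        if len(pa.trees) != len(pb.trees):
            return False
        for ta, tb in zip(pa.trees, pb.trees):
            if ta.parent != tb.parent or ta.assignment != tb.assignment:
                return False
            if not math.isclose(ta.posterior, tb.posterior, rel_tol=rel, abs_tol=rel):
                return False
    return True


# ---------------------------------------------------------------------------
# Pathway catalogs
# ---------------------------------------------------------------------------


def read_pathway_gmt(path) -> PathwayCatalog:
    """Read a GMT gene-set file (name, description, then tab-separated genes)."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortError(
                    f"{path}: line {lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in pathways:
                raise CohortError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise CohortError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    return PathwayCatalog(pathways=pathways)


# ---------------------------------------------------------------------------
# Cohort-level preprocessing
# ---------------------------------------------------------------------------


def filter_hypermutators(
    cohort: list[PatientSample], fraction: float = 0.16
) -> list[PatientSample]:
    """Drop the top ``fraction`` of patients by total mutation count c_j.

    Patients with c_j strictly above the empirical (1 - fraction) quantile are
    removed; ties at the cutoff are retained. Hyper-mutated tumors (e.g.
    MSI/POLE) follow a different mutational process and would distort the
    cohort-level ordering signal.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0 or not cohort:
        return list(cohort)
    counts = np.array([p.c for p in cohort], dtype=float)
    cutoff = float(np.quantile(counts, 1.0 - fraction))
    return [p for p in cohort if p.c <= cutoff]


def make_pair_categories(catalog: PathwayCatalog, pathway_a: str, pathway_b: str) -> PairCategories:
    """Re-organize two (possibly overlapping) pathways into exclusive categories."""
    genes_a = catalog.genes(pathway_a)
    genes_b = catalog.genes(pathway_b)
    raw = {
        A_ONLY: genes_a - genes_b,
        B_ONLY: genes_b - genes_a,
        AB_SHARED: genes_a & genes_b,
    }
    categories = {label: frozenset(g) for label, g in raw.items() if g}
    return PairCategories(pair=(pathway_a, pathway_b), categories=categories)


def restrict_patient_to_pair(patient: PatientSample, categories: PairCategories) -> PatientSample:
    """Keep only mutations whose gene falls in one of the pair's categories.

    Retained mutations are labeled with their category; trees are kept as-is
    (tree reduction to the surviving mutations happens in :mod:`.trees`). The
    result may be empty (c_j = 0), in which case the patient contributes a
    unit likelihood factor downstream.
    """
    kept = []
    for m in patient.mutations:
        label = categories.category_of(m.gene)
        if label is not None:
            kept.append(dataclasses.replace(m, category=label))
    return PatientSample(patient_id=patient.patient_id, mutations=kept, trees=patient.trees)


# ---------------------------------------------------------------------------
# PhyloWGS adapter (best effort)
# ---------------------------------------------------------------------------


def read_phylowgs_summary(
    path,
    patient_id: str,
    genes: Mapping[str, str],
    functional_scores: Mapping[str, float],
    max_trees: int | None = None,
) -> PatientSample:
    """Convert a PhyloWGS-style tree summary JSON into a :class:`PatientSample`.

    Expected dialect (see docs/methods.md): an object with a ``"trees"`` map
    from tree index to ``{"llh": float, "structure": {parent: [children]},
    "mut_assignments": {node: {"ssms": [mutation ids]}}}``. Posteriors are
    obtained by softmax-normalizing log-likelihoods across the reported trees
    (optionally the ``max_trees`` best). The mutation-free normal root
    (node "0") is dropped when it has exactly one child.

    ``genes`` and ``functional_scores`` supply per-mutation annotation that
    the summary itself does not carry.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    entries = sorted(data["trees"].items(), key=lambda kv: -float(kv[1]["llh"]))
    if max_trees is not None:
        entries = entries[:max_trees]
    llh = np.array([float(t["llh"]) for _, t in entries])
    weights = np.exp(llh - llh.max())
    weights /= weights.sum()

    mutations: dict[str, MutationRecord] = {}
    trees: list[CandidateTree] = []
    for (_, t), w in zip(entries, weights):
        parent: dict[str, str | None] = {}
        children: dict[str, list[str]] = {}
        nodes: set[str] = set()
        for par, kids in t["structure"].items():
            nodes.add(str(par))
            children.setdefault(str(par), [])
            for kid in kids:
                parent[str(kid)] = str(par)
                children[str(par)].append(str(kid))
                nodes.add(str(kid))
        for n in nodes:
            parent.setdefault(n, None)
        assignment: dict[str, str] = {}
        for node, ass in t.get("mut_assignments", {}).items():
            for mid in ass.get("ssms", []):
                assignment[str(mid)] = str(node)
        # drop the mutation-free normal root if unambiguous
        root_kids = children.get("0", [])
        if (
            "0" in parent
            and parent["0"] is None
            and len(root_kids) == 1
            and "0" not in set(assignment.values())
        ):
            del parent["0"]
            parent[root_kids[0]] = None
        trees.append(CandidateTree(parent=parent, assignment=assignment, posterior=float(w)))
        for mid in assignment:
            if mid not in mutations:
                mutations[mid] = MutationRecord(
                    mutation_id=mid,
                    gene=str(genes.get(mid, mid)),
                    functional_score=float(functional_scores.get(mid, 0.5)),
                )
    patient = PatientSample(
        patient_id=patient_id, mutations=sorted(mutations.values(), key=lambda m: m.mutation_id),
        trees=trees,
    )
    patient.validate()
    return patient
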