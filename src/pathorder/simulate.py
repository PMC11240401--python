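"""Synthetic cohorts with known ground-truth pathway order.

The generator emulates the structure of phylogeny-annotated tumor cohorts:
per patient, a random subclone tree, functional mutations whose pathway
identities are drawn sequentially from true pivotal rows and placed so that
the sampled temporal order is a linear extension of the tree, passenger
mutations placed uniformly, class-conditional functional impact scores, and
a small set of perturbed alternative candidate trees with Dirichlet
posteriors concentrated on the true tree.

Defaults are chosen so that scores are calibrated: with marginal
r ~ Beta(0.3, 0.3) and functional status S | r ~ Bernoulli(r), the
class-conditional laws are r | S=1 ~ Beta(1.3, 0.3) and
r | S=0 ~ Beta(0.3, 1.3), and P(S=1 | r) = r exactly — the reading the
likelihood gives to the scores.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CandidateTree, MutationRecord, PathwayCatalog, PatientSample

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_pivotal_rows",
    "simulate_cohort",
    "clonality_summary",
    "write_ground_truth",
]

OTHER = "OTHER"


def default_pivotal_rows(n_pathways: int, k0: int = 4, decay: float = 0.25) -> np.ndarray:
    """True pivotal rows planting the listed pathway order.

    Row 1 is geometric over the pathway order (ratio ``decay``; for two
    pathways this is (0.8, 0.2)); later rows mix linearly toward uniform, so
    entropy increases strictly with the step and every row favors earlier
    pathways.
    """
    first = decay ** np.arange(n_pathways, dtype=float)
    first /= first.sum()
    uniform = np.full(n_pathways, 1.0 / n_pathways)
    rows = []
    for k in range(k0):
        t = k / (k0 - 1) if k0 > 1 else 0.0
        rows.append((1.0 - t) * first + t * uniform)
    return np.array(rows)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``mean_mutations`` is the Poisson mean of pathway-relevant mutations per
    patient; ``frac_other`` is the probability that a passenger mutation
    falls outside the cataloged pathways. ``posterior_concentration`` and
    ``temperature`` shape the Dirichlet posteriors over candidate trees (the
    true tree has weight ``posterior_concentration``, alternatives 1; both
    divided by ``temperature``).
    """

    n_patients: int = 200
    pathways: tuple[str, ...] = ("A", "B")
    pivotal_rows: tuple[tuple[float, ...], ...] | None = None
    mean_mutations: float = 5.0
    functional_fraction: float = 0.5
    n_subclones: int = 4
    branching_prob: float = 0.5
    n_trees: int = 3
    posterior_concentration: float = 6.0
    temperature: float = 1.0
    score_params_functional: tuple[float, float] = (1.3, 0.3)
    score_params_nonfunctional: tuple[float, float] = (0.3, 1.3)
    frac_other: float = 0.2
    genes_per_pathway: int = 5
    seed: int = 0

    def resolved_rows(self) -> np.ndarray:
        if self.pivotal_rows is None:
            return default_pivotal_rows(len(self.pathways))
        rows = np.asarray(self.pivotal_rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != len(self.pathways):
            raise ValueError("pivotal_rows must be (k0, n_pathways)")
        if np.any(rows < 0) or np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("pivotal_rows must be row-stochastic")
        return rows

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_subclones < 1:
            raise ValueError("n_subclones must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not self.pathways:
            raise ValueError("at least one pathway is required")
        if not (0.0 <= self.functional_fraction <= 1.0):
            raise ValueError("functional_fraction must be in [0, 1]")
        if not (0.0 <= self.frac_other <= 1.0):
            raise ValueError("frac_other must be in [0, 1]")
        if self.mean_mutations < 0 or self.temperature <= 0:
            raise ValueError("mean_mutations must be >= 0 and temperature > 0")
        self.resolved_rows()


@dataclass(eq=False)
class GroundTruth:
    """What the generator actually planted, for estimator validation."""

    config: dict
    pathway_order: tuple[str, ...]
    pivotal_rows: np.ndarray
    catalog: PathwayCatalog
    functional_ids: dict[str, list[str]]  # patient -> functional mutation ids
    functional_sequence: dict[str, list[str]]  # patient -> temporal pathway sequence
    true_tree_index: dict[str, int]

    def first_functional_pathway(self) -> dict[str, str | None]:
        return {
            pid: (seq[0] if seq else None) for pid, seq in self.functional_sequence.items()
        }


def _sample_tree(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, str | None]:
    parent: dict[str, str | None] = {"s0": None}
    for i in range(1, cfg.n_subclones):
        if i == 1 or rng.random() >= cfg.branching_prob:
            par = f"s{i - 1}"
        else:
            par = f"s{int(rng.integers(0, i))}"
        parent[f"s{i}"] = par
    return parent


def _proper_ancestors(parent: dict[str, str | None], node: str) -> set[str]:
    out = set()
    cur = parent[node]
    while cur is not None:
        out.add(cur)
        cur = parent[cur]
    return out


def _spr_perturb(
    parent: dict[str, str | None], rng: np.random.Generator
) -> dict[str, str | None]:
    """One random subtree-prune-regraft move (identity on 1-2 node trees)."""
    nodes = sorted(parent)
    non_root = [n for n in nodes if parent[n] is not None]
    if not non_root:
        return dict(parent)
    u = non_root[int(rng.integers(0, len(non_root)))]
    in_subtree = {n for n in nodes if u == n or u in _proper_ancestors(parent, n)}
    candidates = [n for n in nodes if n not in in_subtree and n != parent[u]]
    new = dict(parent)
    if candidates:
        new[u] = candidates[int(rng.integers(0, len(candidates)))]
    return new


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[PatientSample], GroundTruth]:
    """Generate a cohort with planted pathway order; deterministic in cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = cfg.resolved_rows()
    k0 = rows.shape[0]
    n_path = len(cfg.pathways)
    gene_pool = {
        pw: tuple(f"{pw}_g{i + 1}" for i in range(cfg.genes_per_pathway))
        for pw in cfg.pathways
    }
    other_pool = tuple(f"{OTHER}_g{i + 1}" for i in range(cfg.genes_per_pathway))
    catalog = PathwayCatalog(
        pathways={pw: frozenset(genes) for pw, genes in gene_pool.items()}
    )

    a1, b1 = cfg.score_params_functional
    a0, b0 = cfg.score_params_nonfunctional
    cohort: list[PatientSample] = []
    functional_ids: dict[str, list[str]] = {}
    functional_sequence: dict[str, list[str]] = {}
    true_tree_index: dict[str, int] = {}

    for j in range(cfg.n_patients):
        pid = f"P{j:04d}"
        parent = _sample_tree(rng, cfg)
        nodes = sorted(parent)
        c = int(rng.poisson(cfg.mean_mutations))
        n_f = int(rng.binomial(c, cfg.functional_fraction)) if c else 0

        mutations: list[MutationRecord] = []
        assignment: dict[str, str] = {}
        f_ids: list[str] = []
        f_seq: list[str] = []
        used_nodes: list[str] = []
        for k in range(n_f):
            row = rows[min(k, k0 - 1)]
            pw = cfg.pathways[int(rng.choice(n_path, p=row))]
            gene = gene_pool[pw][int(rng.integers(0, len(gene_pool[pw])))]
            # place so the sampled order stays a linear extension of the tree:
            # the new node may not be a proper ancestor of any earlier node
            blocked: set[str] = set()
            for un in used_nodes:
                blocked |= _proper_ancestors(parent, un)
            allowed = [n for n in nodes if n not in blocked]
            node = allowed[int(rng.integers(0, len(allowed)))]
            used_nodes.append(node)
            mid = f"{pid}_m{len(mutations)}"
            score = float(rng.beta(a1, b1))
            mutations.append(MutationRecord(mutation_id=mid, gene=gene, functional_score=score))
            assignment[mid] = node
            f_ids.append(mid)
            f_seq.append(pw)
        for _ in range(c - n_f):
            if rng.random() < cfg.frac_other:
                gene = other_pool[int(rng.integers(0, len(other_pool)))]
            else:
                pw = cfg.pathways[int(rng.integers(0, n_path))]
                gene = gene_pool[pw][int(rng.integers(0, len(gene_pool[pw])))]
            node = nodes[int(rng.integers(0, len(nodes)))]
            mid = f"{pid}_m{len(mutations)}"
            score = float(rng.beta(a0, b0))
            mutations.append(MutationRecord(mutation_id=mid, gene=gene, functional_score=score))
            assignment[mid] = node

        parents = [parent] + [_spr_perturb(parent, rng) for _ in range(cfg.n_trees - 1)]
        alpha = np.array(
            [cfg.posterior_concentration] + [1.0] * (cfg.n_trees - 1)
        ) / cfg.temperature
        posteriors = rng.dirichlet(alpha) if cfg.n_trees > 1 else np.array([1.0])
        trees = [
            CandidateTree(parent=dict(par), assignment=dict(assignment), posterior=float(w))
            for par, w in zip(parents, posteriors)
        ]
        patient = PatientSample(patient_id=pid, mutations=mutations, trees=trees)
        patient.validate()
        cohort.append(patient)
        functional_ids[pid] = f_ids
        functional_sequence[pid] = f_seq
        true_tree_index[pid] = 0

    truth = GroundTruth(
        config=dataclasses.asdict(cfg),
        pathway_order=cfg.pathways,
        pivotal_rows=rows,
        catalog=catalog,
        functional_ids=functional_ids,
        functional_sequence=functional_sequence,
        true_tree_index=true_tree_index,
    )
    return cohort, truth


def clonality_summary(
    cohort: Sequence[PatientSample], catalog: PathwayCatalog
) -> dict[str, dict | None]:
    """Per-pathway clonal fraction: share of carriers whose maximum-posterior
    tree places at least one pathway mutation on the trunk (root) node.

    Pathways absent from the cohort are reported as None. Returns fraction,
    binomial standard error, and the number of carriers per pathway.
    """
    out: dict[str, dict | None] = {}
    for pw, genes in catalog.pathways.items():
        flags: list[bool] = []
        for p in cohort:
            hits = [m.mutation_id for m in p.mutations if m.gene in genes]
            if not hits or not p.trees:
                continue
            best = max(p.trees, key=lambda t: t.posterior)
            root = best.root
            flags.append(any(best.assignment.get(mid) == root for mid in hits))
        if not flags:
            out[pw] = None
            continue
        n = len(flags)
        frac = sum(flags) / n
        out[pw] = {"fraction": frac, "se": math.sqrt(frac * (1 - frac) / n), "n": n}
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "config": truth.config,
        "pathway_order": list(truth.pathway_order),
        "pivotal_rows": truth.pivotal_rows.tolist(),
        "catalog": {pw: sorted(genes) for pw, genes in truth.catalog.pathways.items()},
        "functional_ids": truth.functional_ids,
        "functional_sequence": truth.functional_sequence,
        "true_tree_index": truth.true_tree_index,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)
        fh.write("\n")
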