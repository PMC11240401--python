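"""Partial-order graph assembly from pairwise order probabilities.

Each analyzed pathway pair yields directed probabilities P(A<B) and P(B<A).
The summary graph keeps, per pair, the more probable direction if it clears
an edge threshold (default 0.4), breaks any cycles arising from intransitive
pairwise estimates by dropping the weakest edge per cycle, removes edges
parallel to longer directed paths (transitive reduction), and layers nodes
by longest incoming path for a layered drawing, exported as DOT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import pandas as pd

from .model import PairOrderResult

__all__ = [
    "PartialOrderGraph",
    "threshold_edges",
    "build_graph",
    "layer_nodes",
    "export_dot",
    "to_dot",
    "write_pair_matrix",
    "read_pair_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_EDGE_THRESHOLD = 0.4
#: DOT pen width of a probability-1 edge; widths scale proportionally.
PENWIDTH_SCALE = 6.0


@dataclass(eq=False)
class PartialOrderGraph:
    """Directed pathway-precedence graph with optional layer assignment."""

    graph: nx.DiGraph
    layers: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((u, v, d["weight"]) for u, v, d in self.graph.edges(data=True))


def threshold_edges(
    results: Mapping[tuple[str, str], PairOrderResult],
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> dict[tuple[str, str], float]:
    """Per unordered pair, the winning directed edge if it clears the threshold.

    This stage is anti-monotone in the threshold: raising it never adds an
    edge. Cycle breaking and transitive reduction happen in
    :func:`build_graph`.
    """
    seen: set[frozenset[str]] = set()
    edges: dict[tuple[str, str], float] = {}
    for (a, b), res in sorted(results.items()):
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate results for pair {sorted(key)}")
        seen.add(key)
        if a == b:
            continue
        pa, pb = res.p_a_before_b, res.p_b_before_a
        src, dst, w = (a, b, pa) if pa >= pb else (b, a, pb)
        if w >= threshold:
            edges[(src, dst)] = float(w)
    return edges


def build_graph(
    results: Mapping[tuple[str, str], PairOrderResult],
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> PartialOrderGraph:
    """Assemble and prune the pairwise results into an acyclic summary graph.

    Per unordered pair, at most one directed edge survives (the direction
    with the larger probability, if >= threshold). Cycles among retained
    edges are broken by removing the lowest-weight edge in each cycle
    (logged); finally edges parallel to a longer directed path are removed.
    """
    g = nx.DiGraph()
    for a, b in results:
        g.add_node(a)
        g.add_node(b)
    for (src, dst), w in threshold_edges(results, threshold).items():
        g.add_edge(src, dst, weight=w)

    # break cycles from intransitive pairwise estimates
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        u, v = min(
            ((u, v) for u, v, *_ in cycle),
            key=lambda e: (g.edges[e]["weight"], e),
        )
        logger.warning(
            "cycle %s broken by removing lowest-weight edge %s->%s (%.3f)",
            [f"{x}->{y}" for x, y, *_ in cycle],
            u,
            v,
            g.edges[u, v]["weight"],
        )
        g.remove_edge(u, v)

    # transitive reduction, keeping weights
    tr = nx.transitive_reduction(g)
    pruned = nx.DiGraph()
    pruned.add_nodes_from(sorted(g.nodes))
    for u, v in tr.edges:
        pruned.add_edge(u, v, weight=g.edges[u, v]["weight"])
    return layer_nodes(PartialOrderGraph(graph=pruned))


def layer_nodes(pog: PartialOrderGraph) -> PartialOrderGraph:
    """Assign longest-incoming-path layers (sources at layer 0)."""
    g = pog.graph
    if not nx.is_directed_acyclic_graph(g):
        raise RuntimeError("internal error: pruned graph contains a cycle")
    layers = {n: 0 for n in g.nodes}
    for n in nx.topological_sort(g):
        for pred in g.predecessors(n):
            layers[n] = max(layers[n], layers[pred] + 1)
    pog.layers = layers
    return pog


def to_dot(pog: PartialOrderGraph) -> str:
    """Deterministic DOT text; edge pen width proportional to probability."""
    lines = ["digraph pathway_order {", "  rankdir=TB;"]
    by_layer: dict[int, list[str]] = {}
    for n in pog.nodes:
        by_layer.setdefault(pog.layers.get(n, 0), []).append(n)
    for layer in sorted(by_layer):
        members = " ".join(f'"{n}";' for n in sorted(by_layer[layer]))
        lines.append(f"  {{ rank=same; {members} }}")
    for u, v, w in pog.edges:
        lines.append(
            f'  "{u}" -> "{v}" [penwidth={PENWIDTH_SCALE * w:.3f}, label="{w:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_dot(pog: PartialOrderGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_dot(pog))


def write_pair_matrix(results: Mapping[tuple[str, str], PairOrderResult], path) -> None:
    """Serialize pairwise probabilities as long-form CSV (both directions + tie)."""
    records = [
        {
            "pathway_a": a,
            "pathway_b": b,
            "p_a_before_b": res.p_a_before_b,
            "p_b_before_a": res.p_b_before_a,
            "p_tie": res.p_tie,
            "c": res.c,
            "uninformative": res.uninformative,
        }
        for (a, b), res in sorted(results.items())
    ]
    pd.DataFrame.from_records(
        records,
        columns=[
            "pathway_a",
            "pathway_b",
            "p_a_before_b",
            "p_b_before_a",
            "p_tie",
            "c",
            "uninformative",
        ],
    ).to_csv(path, index=False)


def read_pair_matrix(path) -> dict[tuple[str, str], PairOrderResult]:
    df = pd.read_csv(path)
    required = {"pathway_a", "pathway_b", "p_a_before_b", "p_b_before_a", "p_tie"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair matrix {path} missing columns {sorted(missing)}")
    out: dict[tuple[str, str], PairOrderResult] = {}
    for rec in df.to_dict("records"):
        out[(str(rec["pathway_a"]), str(rec["pathway_b"]))] = PairOrderResult(
            p_a_before_b=float(rec["p_a_before_b"]),
            p_b_before_a=float(rec["p_b_before_a"]),
            p_tie=float(rec["p_tie"]),
            c=int(rec.get("c", 0) or 0),
            uninformative=bool(rec.get("uninformative", False)),
        )
    return out
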