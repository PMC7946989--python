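"""Co-predictive networks from rule models.

Nodes are (feature, level) pairs; an edge accumulates RS x RA over every rule
containing both conditions.  Includes unity-based normalization, hub
detection, top-N node / top-fraction edge filtering, an exact one-dimensional
2-means split for top co-predictors, and term-fraction profiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .rules import Rule

__all__ = [
    "CoPredNetwork",
    "build_network",
    "normalize_connections",
    "top_nodes",
    "detect_hubs",
    "kmeans_top_copredictors",
    "term_fraction",
]

Node = tuple[str, int]


@dataclass
class CoPredNetwork:
    """Undirected graph of (feature, level) nodes with connection weights.

    Node ``raw`` equals the sum of incident edge ``raw`` weights; ``norm`` is
    min-max scaled within the network (all-equal collapses to 1.0).
    """

    graph: nx.Graph
    provenance: str = "all"

    @property
    def nodes(self) -> list[Node]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[Node, Node]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def node_raw(self, node: Node) -> float:
        return self.graph.nodes[node]["raw"]

    def edge_raw(self, a: Node, b: Node) -> float:
        return self.graph.edges[a, b]["raw"]

    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.graph["provenance"] = self.provenance
        for node, data in self.graph.nodes(data=True):
            g.add_node(f"{node[0]}={node[1]}", feature=node[0], level=node[1], **data)
        for a, b, data in self.graph.edges(data=True):
            g.add_edge(f"{a[0]}={a[1]}", f"{b[0]}={b[1]}", **data)
        nx.write_graphml(g, path)

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\traw\tnorm\n")
            for a, b in self.edges:
                d = self.graph.edges[a, b]
                fh.write(f"{a[0]}={a[1]}\t{b[0]}={b[1]}\t{d['raw']!r}\t{d.get('norm', '')}\n")


def build_network(
    rules: Iterable[Rule],
    class_filter: str | None = None,
    support: str = "rhs",
    include_isolated: bool = False,
    provenance: str | None = None,
) -> CoPredNetwork:
    """Expand each multi-condition rule into its condition pairs.

    Every unordered pair of conditions of a rule contributes
    ``RS x RA`` (RS = ``rs_rhs`` by default, ``rs_lhs`` via ``support``) to
    that edge.  Single-condition rules contribute isolated zero-weight nodes,
    dropped unless ``include_isolated``.  ``class_filter`` restricts to rules
    of one decision class.
    """
    if support not in ("rhs", "lhs"):
        raise ValueError("support must be 'rhs' or 'lhs'")
    g = nx.Graph()
    class_weight: dict[Node, dict[str, float]] = {}
    for rule in rules:
        if class_filter is not None and rule.decision != class_filter:
            continue
        rs = rule.rs_rhs if support == "rhs" else rule.rs_lhs
        weight = rs * rule.ra
        conds = rule.sorted_conditions()
        for node in conds:
            class_weight.setdefault(node, {})
            class_weight[node][rule.decision] = class_weight[node].get(rule.decision, 0.0) + weight
        if len(conds) < 2:
            if include_isolated:
                g.add_node(conds[0])
            continue
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a, b = conds[i], conds[j]
                if g.has_edge(a, b):
                    g.edges[a, b]["raw"] += weight
                else:
                    g.add_edge(a, b, raw=weight)
    for node in g.nodes:
        g.nodes[node]["raw"] = float(sum(d["raw"] for _, _, d in g.edges(node, data=True)))
        g.nodes[node]["is_hub"] = False
        cw = class_weight.get(node, {})
        g.nodes[node]["decision_class"] = (
            min(cw, key=lambda c: (-cw[c], c)) if cw else (class_filter or "")
        )
    return CoPredNetwork(graph=g, provenance=provenance or (class_filter or "all"))


def _minmax(values: np.ndarray) -> np.ndarray:
    if values.size == 0:
        return values
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def normalize_connections(net: CoPredNetwork) -> CoPredNetwork:
    """Unity-based (min-max) normalization of edge and node raw connections."""
    g = net.graph
    edges = list(g.edges)
    enorm = _minmax(np.array([g.edges[e]["raw"] for e in edges]))
    for e, v in zip(edges, enorm):
        g.edges[e]["norm"] = float(v)
    nodes = list(g.nodes)
    nnorm = _minmax(np.array([g.nodes[n]["raw"] for n in nodes]))
    for n, v in zip(nodes, nnorm):
        g.nodes[n]["norm"] = float(v)
    return net


def top_nodes(net: CoPredNetwork, n: int, fraction: float | None = None) -> CoPredNetwork:
    """Induced subgraph on the ``n`` most strongly connected nodes, optionally
    then keeping only the top ``fraction`` of the remaining edges by raw weight."""
    if n < 1:
        raise ValueError("n must be >= 1")
    g = net.graph
    if n > g.number_of_nodes():
        warnings.warn("n exceeds node count: returning the whole network", stacklevel=2)
        n = g.number_of_nodes()
    ranked = sorted(g.nodes, key=lambda node: (-g.nodes[node]["raw"], node))
    keep = set(ranked[:n])
    sub = g.subgraph(keep).copy()
    if fraction is not None:
        edges = sorted(sub.edges, key=lambda e: (-sub.edges[e]["raw"], tuple(sorted(e))))
        n_keep = int(np.ceil(fraction * len(edges)))
        for e in edges[n_keep:]:
            sub.remove_edge(*e)
    return CoPredNetwork(graph=sub, provenance=net.provenance)


def detect_hubs(net: CoPredNetwork, degree_quantile: float = 0.9) -> CoPredNetwork:
    """Flag hub nodes: degree positive and >= the ``degree_quantile`` of the
    distinct positive node degrees (ties at the threshold are included)."""
    g = net.graph
    degrees = np.array(sorted({d for _, d in g.degree if d > 0}))
    if degrees.size == 0:
        for node in g.nodes:
            g.nodes[node]["is_hub"] = False
        return net
    threshold = float(np.quantile(degrees, degree_quantile, method="higher"))
    for node in g.nodes:
        g.nodes[node]["is_hub"] = g.degree[node] >= threshold and g.degree[node] > 0
    return net


def kmeans_top_copredictors(node_connections: dict[Node, float] | dict[str, float]) -> set[str]:
    """Exact one-dimensional 2-means on node connection values.

    All split points of the sorted values are scanned and the within-cluster
    sum of squares minimized; nodes in the higher-mean cluster are returned
    with discretization levels collapsed to feature ids.
    """
    if len(node_connections) < 2:
        raise ValueError("need at least 2 nodes")
    items = sorted(node_connections.items(), key=lambda kv: kv[1])
    values = np.array([v for _, v in items], dtype=float)
    if values.min() == values.max():
        raise ValueError("no threshold separable: all connection values identical")
    best_split, best_ss = None, np.inf
    for split in range(1, len(values)):
        lo, hi = values[:split], values[split:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss = ss
            best_split = split
    top = [k for k, _ in items[best_split:]]
    return {k[0] if isinstance(k, tuple) else str(k).split("=")[0] for k in top}


def term_fraction(gene_set: Sequence[str] | set[str], term_genes: Sequence[str] | set[str]) -> float:
    """Fraction of ``gene_set`` contained in ``term_genes``."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    return len(genes & set(term_genes)) / len(genes)
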