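"""Multimorbidity graph construction and node centralities.

The multimorbidity network is an undirected graph whose nodes are diseases
(with chapter and prevalence attributes) and whose edges are the selected
comorbidity patterns (with odds ratio, p-value, and co-occurrence
frequency).  Seven node metrics are computed on the unweighted graph:
degree, maximal clique centrality (MCC), closeness, local clustering
coefficient, betweenness, PageRank, and eigenvector centrality.

MCC(v) is the sum over maximal cliques C of size >= 2 containing v of
(|C|-1)!; when v's neighborhood contains no internal edge every maximal
clique through v is a single edge and MCC reduces to degree(v) (an
isolated node scores 0).  Maximal cliques come from NetworkX's pivoting
Bron-Kerbosch enumeration.

Conventions for disconnected graphs: closeness uses the Wasserman-Faust
component scaling; betweenness is computed on the full graph with raw
(unnormalized) pair counts; eigenvector centrality is computed on the
largest connected component, zero elsewhere, then max-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from . import icd10
from .screening import PatternResult

__all__ = [
    "NodeMetrics",
    "build_network",
    "compute_metrics",
    "edge_table",
    "enumerate_maximal_cliques",
    "hub_associated_subnetwork",
    "mcc",
    "metrics_frame",
    "node_table",
    "write_graphml",
]


@dataclass(frozen=True)
class NodeMetrics:
    """The seven centrality values of one disease node."""

    degree: int
    mcc: int
    closeness: float
    clustering_coefficient: float
    betweenness: float
    pagerank: float
    eigencentrality: float


def build_network(
    selected: list[PatternResult],
    prevalence: dict[str, tuple[int, float]] | None = None,
    label: str = "network",
) -> nx.Graph:
    """Assemble the multimorbidity graph from selected patterns.

    Every pattern must carry ``selected=True``; nodes are the union of
    pattern endpoints with chapter/prevalence attributes, edges carry the
    odds ratio, p-value, and frequency.
    """
    graph = nx.Graph(label=label)
    prevalence = prevalence or {}
    for result in selected:
        if not result.selected:
            raise ValueError(
                f"pattern {result.counts.pair} is not flagged selected")
        a, b = result.counts.pair
        for code in (a, b):
            if code not in graph:
                count, prev = prevalence.get(code, (0, float("nan")))
                graph.add_node(code, chapter=icd10.chapter(code) or 0,
                               prevalence=prev, count=count)
        graph.add_edge(a, b, odds_ratio=result.odds_ratio,
                       p_value=result.p_value,
                       frequency=result.counts.frequency)
    return graph


def enumerate_maximal_cliques(graph: nx.Graph) -> list[frozenset[str]]:
    """All maximal cliques (pivoting Bron-Kerbosch via NetworkX).

    Isolated nodes yield singleton maximal cliques.  Returned in a
    deterministic sorted order.
    """
    cliques = [frozenset(c) for c in nx.find_cliques(graph)] if len(graph) else []
    return sorted(cliques, key=lambda c: (len(c), tuple(sorted(c))))


def mcc(graph: nx.Graph, node: str,
        cliques: list[frozenset[str]] | None = None) -> int:
    """Maximal clique centrality of ``node`` (exact integer arithmetic)."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    if cliques is None:
        cliques = enumerate_maximal_cliques(graph)
    return sum(math.factorial(len(c) - 1)
               for c in cliques if len(c) >= 2 and node in c)


def compute_metrics(graph: nx.Graph,
                    betweenness_normalized: bool = False
                    ) -> dict[str, NodeMetrics]:
    """All seven node metrics for every node of the graph."""
    if len(graph) == 0:
        return {}
    cliques = enumerate_maximal_cliques(graph)
    mcc_scores = {v: 0 for v in graph}
    for clique in cliques:
        if len(clique) >= 2:
            weight = math.factorial(len(clique) - 1)
            for v in clique:
                mcc_scores[v] += weight
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    clustering = nx.clustering(graph)
    betweenness = nx.betweenness_centrality(
        graph, normalized=betweenness_normalized)
    pagerank = nx.pagerank(graph, alpha=0.85, tol=1e-9, max_iter=1000)
    eigen = _eigencentrality(graph)
    return {
        v: NodeMetrics(
            degree=graph.degree(v), mcc=mcc_scores[v],
            closeness=closeness[v], clustering_coefficient=clustering[v],
            betweenness=betweenness[v], pagerank=pagerank[v],
            eigencentrality=eigen[v])
        for v in sorted(graph.nodes)
    }


def _eigencentrality(graph: nx.Graph) -> dict[str, float]:
    # principal eigenvector of the largest component, 0 elsewhere, max = 1
    scores = dict.fromkeys(graph, 0.0)
    giant = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)))
    if len(giant) == 1:
        scores[next(iter(giant))] = 1.0
        return scores
    import numpy as np

    order = sorted(giant)
    adjacency = nx.to_numpy_array(graph.subgraph(giant), nodelist=order)
    _, vectors = np.linalg.eigh(adjacency)  # symmetric; last column is principal
    principal = np.abs(vectors[:, -1])
    principal /= principal.max()
    for v, val in zip(order, principal):
        scores[v] = float(val)
    return scores


def hub_associated_subnetwork(graph: nx.Graph, hubs: list[str]) -> nx.Graph:
    """Subgraph of all edges incident to at least one hub, plus endpoints.

    A hub with no edges contributes itself as an isolated node.  Node and
    edge attributes are preserved.
    """
    missing = [h for h in hubs if h not in graph]
    if missing:
        raise KeyError(f"hub(s) not in network: {missing}")
    hub_set = set(hubs)
    sub = nx.Graph(label=f"{graph.graph.get('label', 'network')}_hub_associated")
    for h in hubs:
        sub.add_node(h, **graph.nodes[h])
    for u, v, attrs in graph.edges(data=True):
        if u in hub_set or v in hub_set:
            for node in (u, v):
                if node not in sub:
                    sub.add_node(node, **graph.nodes[node])
            sub.add_edge(u, v, **attrs)
    return sub


def metrics_frame(graph: nx.Graph, **kwargs) -> pd.DataFrame:
    """Node metric table, one row per disease in lexicographic order."""
    metrics = compute_metrics(graph, **kwargs)
    rows = [{"code": v, **vars(m)} for v, m in metrics.items()]
    return pd.DataFrame(rows, columns=["code", "degree", "mcc", "closeness",
                                       "clustering_coefficient", "betweenness",
                                       "pagerank", "eigencentrality"])


def node_table(graph: nx.Graph, **kwargs) -> pd.DataFrame:
    """Node table with attributes and the seven metrics."""
    frame = metrics_frame(graph, **kwargs)
    frame.insert(1, "chapter", [graph.nodes[v].get("chapter") for v in frame["code"]])
    frame.insert(2, "prevalence",
                 [graph.nodes[v].get("prevalence") for v in frame["code"]])
    return frame


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge table: canonical pair, odds ratio, p-value, frequency."""
    rows = []
    for u, v, attrs in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append({"code_i": a, "code_j": b,
                     "odds_ratio": attrs.get("odds_ratio"),
                     "p_value": attrs.get("p_value"),
                     "frequency": attrs.get("frequency")})
    frame = pd.DataFrame(rows, columns=["code_i", "code_j", "odds_ratio",
                                        "p_value", "frequency"])
    return frame.sort_values(["code_i", "code_j"]).reset_index(drop=True)


def write_graphml(graph: nx.Graph, path: str | Path,
                  with_metrics: bool = True) -> None:
    """GraphML export with node attributes (chapter, prevalence, metrics)."""
    out = graph.copy()
    if with_metrics and len(out):
        for v, m in compute_metrics(out).items():
            out.nodes[v].update(vars(m))
    # GraphML cannot serialize NaN prevalence for nodes without a map entry
    for _, attrs in out.nodes(data=True):
        if "prevalence" in attrs and pd.isna(attrs["prevalence"]):
            del attrs["prevalence"]
    nx.write_graphml(out, str(path))
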