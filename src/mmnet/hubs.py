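"""Hub diseases and their associated networks.

Hub diseases are the top-k nodes of a complete multimorbidity network by
degree (k = 10 by default), with degree ties broken by higher disease
prevalence and residual ties by code order so runs are reproducible.  The
hub-associated network collects every comorbidity pattern incident to at
least one hub; coverage statistics express its size as percentages of the
complete network's edges, total pattern frequency, and nodes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .cohort import Cohort
from .network import build_network, hub_associated_subnetwork
from .screening import (PatternResult, SelectionReport, disease_prevalence,
                        screen_cohort)

__all__ = ["HubReport", "coverage_stats", "hub_pipeline", "identify_hubs"]


@dataclass
class HubReport:
    """Hubs, their associated network, and the three coverage percentages."""

    label: str
    hubs: list[tuple[str, int, float]]  # (code, degree, prevalence)
    complete_network: nx.Graph
    associated_network: nx.Graph
    unique_pattern_coverage: float
    frequency_coverage: float
    node_coverage: float
    patterns: list[PatternResult] = field(default_factory=list)
    selection: SelectionReport | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "hubs": [{"code": c, "degree": d, "prevalence": p}
                     for c, d, p in self.hubs],
            "n_nodes": self.complete_network.number_of_nodes(),
            "n_edges": self.complete_network.number_of_edges(),
            "n_nodes_associated": self.associated_network.number_of_nodes(),
            "n_edges_associated": self.associated_network.number_of_edges(),
            "unique_pattern_coverage_pct": round(self.unique_pattern_coverage, 2),
            "frequency_coverage_pct": round(self.frequency_coverage, 2),
            "node_coverage_pct": round(self.node_coverage, 2),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def identify_hubs(
    graph: nx.Graph,
    k: int = 10,
    prevalence: dict[str, tuple[int, float]] | None = None,
) -> list[tuple[str, int, float]]:
    """The k nodes with the most connections, as (code, degree, prevalence).

    Ranking is degree descending, ties broken by prevalence descending,
    residual ties by lexicographic code order.  Prevalence defaults to the
    node attribute attached by :func:`~mmnet.network.build_network`.
    """
    def prev_of(code: str) -> float:
        if prevalence is not None:
            return prevalence.get(code, (0, 0.0))[1]
        value = graph.nodes[code].get("prevalence", 0.0)
        return 0.0 if value != value else value  # NaN -> 0

    if graph.number_of_nodes() < k:
        warnings.warn(f"network has {graph.number_of_nodes()} nodes, "
                      f"fewer than k={k}; returning all", stacklevel=2)
    ranked = sorted(graph.nodes,
                    key=lambda v: (-graph.degree(v), -prev_of(v), v))
    return [(v, graph.degree(v), prev_of(v)) for v in ranked[:k]]


def _total_frequency(graph: nx.Graph) -> int:
    return sum(attrs.get("frequency", 0) for _, _, attrs in graph.edges(data=True))


def coverage_stats(complete: nx.Graph, associated: nx.Graph
                   ) -> tuple[float, float, float]:
    """Percent of edges, total pattern frequency, and nodes covered.

    Returns (unique_pattern_coverage, frequency_coverage, node_coverage),
    each as 100 * associated / complete on the respective quantity.
    """
    n_edges = complete.number_of_edges()
    if complete.number_of_nodes() == 0 or n_edges == 0:
        raise ValueError("complete network is empty")
    unique = 100.0 * associated.number_of_edges() / n_edges
    freq = 100.0 * _total_frequency(associated) / _total_frequency(complete)
    nodes = 100.0 * associated.number_of_nodes() / complete.number_of_nodes()
    return unique, freq, nodes


def hub_pipeline(cohort: Cohort, k: int = 10, alpha: float = 0.05,
                 prevalence_floor: float = 1e-4) -> HubReport:
    """Screen a cohort, build its network, and report hubs with coverage.

    An empty selection yields an empty report with a warning rather than
    an error, mirroring a null cohort.
    """
    results, selection = screen_cohort(cohort, alpha=alpha,
                                       prevalence_floor=prevalence_floor)
    prevalence = disease_prevalence(cohort)
    chosen = [r for r in results if r.selected]
    complete = build_network(chosen, prevalence, label=cohort.label)
    if complete.number_of_edges() == 0:
        warnings.warn(f"no edges selected for {cohort.label}; empty report",
                      stacklevel=2)
        return HubReport(label=cohort.label, hubs=[],
                         complete_network=complete,
                         associated_network=nx.Graph(),
                         unique_pattern_coverage=0.0, frequency_coverage=0.0,
                         node_coverage=0.0, patterns=results,
                         selection=selection)
    hubs = identify_hubs(complete, k=k, prevalence=prevalence)
    associated = hub_associated_subnetwork(complete, [h for h, _, _ in hubs])
    unique, freq, nodes = coverage_stats(complete, associated)
    return HubReport(label=cohort.label, hubs=hubs,
                     complete_network=complete, associated_network=associated,
                     unique_pattern_coverage=unique, frequency_coverage=freq,
                     node_coverage=nodes, patterns=results,
                     selection=selection)
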