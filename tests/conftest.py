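from datetime import date

import networkx as nx
import pytest

from mmnet.cohort import Cohort, InpatientRecord


def make_record(pid="P1", when=date(2010, 1, 1), age=45, sex="female",
                codes=("I10",)):
    return InpatientRecord(patient_id=pid, admission_date=when, age=age,
                           sex=sex, codes=frozenset(codes))


@pytest.fixture
def tiny_cohort():
    """Four patients, two diseases co-occurring in one record."""
    records = [
        make_record("P1", codes=("A00", "B00")),
        make_record("P2", codes=("A00",), sex="male"),
        make_record("P3", codes=("B00",), sex="male"),
        make_record("P4", codes=("I10",)),
    ]
    return Cohort(records=records, label="tiny")


@pytest.fixture
def k4_pendant():
    """Complete graph on {a,b,c,d} plus pendant p attached to d."""
    g = nx.complete_graph(["a", "b", "c", "d"])
    g.add_edge("d", "p")
    return g


def brute_force_maximal_cliques(graph):
    """Exhaustive subset enumeration; usable for graphs up to ~12 nodes."""
    from itertools import combinations

    nodes = list(graph.nodes)
    cliques = []
    for size in range(1, len(nodes) + 1):
        for subset in combinations(nodes, size):
            if all(graph.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return [c for c in cliques
            if not any(c < other for other in cliques)]
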