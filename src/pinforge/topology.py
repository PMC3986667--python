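"""Topological features of an undirected PPI network.

The seven reported features are node count, edge count, diameter,
average path length over connected pairs, mean clustering coefficient,
average degree (self-loops counted twice) and index aggregation (the
fraction of all nodes inside the largest weakly connected component).
Networks here are undirected, so strongly and weakly connected
components coincide; only the weak notion is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import UsageError


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    diameter: int
    average_path_length: float
    clustering_coefficient: float
    average_degree: float
    index_aggregation: float
    components: list[set[str]]


def weakly_connected_components(graph: nx.Graph) -> list[set]:
    """Connected components, largest first (ties broken lexically)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(map(str, c))))


def diameter_and_apl(component: nx.Graph) -> tuple[int, float]:
    """BFS hop diameter and mean shortest path over connected pairs.

    The caller must pass a connected graph with at least 2 nodes; the
    mean is over unordered pairs, which for an undirected graph equals
    the mean over ordered pairs.
    """
    if component.number_of_nodes() < 2:
        raise UsageError("diameter needs at least 2 nodes")
    if not nx.is_connected(component):
        raise UsageError("diameter_and_apl requires a connected component")
    ecc = nx.eccentricity(component)
    diameter = max(ecc.values())
    apl = nx.average_shortest_path_length(component)
    return int(diameter), float(apl)


def clustering_coefficient(graph: nx.Graph, node) -> float:
    """C_v = 2 e_v / (k_v (k_v - 1)); 0 when v has fewer than 2 neighbors.

    e_v counts edges among the neighbors of v.  Self-loops are excluded
    from neighborhoods.
    """
    if node not in graph:
        raise UsageError(f"unknown node {node!r}")
    simple = _without_self_loops(graph)
    return float(nx.clustering(simple, node))


def network_clustering(graph: nx.Graph, include_low_degree: bool = True) -> float:
    """Unweighted mean of C_v over nodes.

    ``include_low_degree=False`` restricts the mean to nodes with
    degree >= 2 (the convention is not universal; the inclusive mean is
    the default).
    """
    simple = _without_self_loops(graph)
    if simple.number_of_nodes() == 0:
        raise UsageError("empty network")
    values = nx.clustering(simple)
    if not include_low_degree:
        values = {v: c for v, c in values.items() if simple.degree(v) >= 2}
        if not values:
            return 0.0
    return float(sum(values.values()) / len(values))


def _without_self_loops(graph: nx.Graph) -> nx.Graph:
    if nx.number_of_selfloops(graph) == 0:
        return graph
    simple = graph.copy()
    simple.remove_edges_from(nx.selfloop_edges(simple))
    return simple


def average_degree(graph: nx.Graph) -> float:
    """Mean node degree, self-loops counted twice."""
    if graph.number_of_nodes() == 0:
        raise UsageError("empty network")
    degrees = dict(graph.degree())
    return float(sum(degrees.values()) / len(degrees))


def index_aggregation(graph: nx.Graph) -> float:
    """|largest component| / |V|."""
    if graph.number_of_nodes() == 0:
        raise UsageError("empty network")
    comps = weakly_connected_components(graph)
    return len(comps[0]) / graph.number_of_nodes()


def hubs(graph: nx.Graph, min_degree: int = 33) -> list:
    """Nodes with degree strictly greater than ``min_degree``.

    Sorted by degree descending, ties lexicographic.
    """
    selected = [(v, d) for v, d in graph.degree() if d > min_degree]
    selected.sort(key=lambda vd: (-vd[1], str(vd[0])))
    return [v for v, _ in selected]


def topology_report(graph: nx.Graph, lwcc_only: bool = False) -> TopologyReport:
    """Compute all reported features; optionally restrict to the LWCC."""
    if graph.number_of_nodes() == 0:
        raise UsageError("empty network")
    components = weakly_connected_components(graph)
    target = graph.subgraph(components[0]).copy() if lwcc_only else graph
    if target.number_of_nodes() >= 2 and nx.is_connected(target):
        diameter, apl = diameter_and_apl(target)
    else:
        lwcc = target.subgraph(max(nx.connected_components(target), key=len))
        if lwcc.number_of_nodes() >= 2:
            diameter, apl = diameter_and_apl(lwcc.copy())
        else:
            diameter, apl = 0, 0.0
    return TopologyReport(
        n_nodes=target.number_of_nodes(),
        n_edges=target.number_of_edges(),
        diameter=diameter,
        average_path_length=apl,
        clustering_coefficient=network_clustering(target),
        average_degree=average_degree(target),
        index_aggregation=index_aggregation(graph),
        components=components,
    )
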