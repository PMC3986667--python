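"""GO-defined sub-network extraction and evolutionary-origin analysis.

Signaling proteins are those annotated (directly or through is_a
ancestors) with the "signaling" biological process, GO:0023052.  The
evolutionary origin of a protein or interaction is the earliest stage —
primitive (P) < bilaterian (B) < vertebrate (V) — among the source
organisms it occurs in; a complete interaction (two proteins plus the
edge) originates at the *latest* of its three component origins, the
stage at which the last piece appeared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import UsageError
from .io_formats import AnnotationTable, GoDag, canonical_pair

logger = logging.getLogger(__name__)

SIGNALING_GO_ID = "GO:0023052"

STAGES = ("P", "B", "V")
_STAGE_ORDER = {stage: i for i, stage in enumerate(STAGES)}

StageMap = Mapping[str, str]  # organism -> P/B/V


def propagate_annotations(
    annotations: AnnotationTable, dag: GoDag
) -> AnnotationTable:
    """Close each protein's term set under is_a ancestors (true path)."""
    closed: AnnotationTable = {}
    for protein, terms in annotations.items():
        out: set[str] = set()
        for term in terms:
            if term not in dag:
                raise UsageError(f"annotation term {term} not in DAG")
            out.add(term)
            out |= dag.ancestors(term)
        closed[protein] = out
    return closed


@dataclass
class GoSubnetwork:
    go_id: str
    seeds: set[str]
    isolated_seeds: set[str]
    graph: nx.Graph
    expanded: bool = False

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()


def extract_go_subnetwork(
    graph: nx.Graph,
    annotations: AnnotationTable,
    go_id: str,
    dag: GoDag,
    expand_neighbors: bool = False,
    direct_only: bool = False,
) -> GoSubnetwork:
    """Extract the sub-network of proteins annotated with ``go_id``.

    Seeds are network proteins whose (ancestor-closed, unless
    ``direct_only``) annotation contains ``go_id``.  The base sub-network
    is the seeds plus edges among seeds; seeds with no such edge are
    counted as isolated.  With ``expand_neighbors`` every neighbor of a
    seed joins, together with all seed-incident edges.
    """
    if go_id not in dag:
        raise UsageError(f"GO id {go_id} absent from the DAG")
    effective = annotations if direct_only else propagate_annotations(annotations, dag)
    seeds = {
        p for p in graph.nodes if go_id in effective.get(p, set())
    }
    sub = nx.Graph()
    sub.add_nodes_from(seeds)
    for a, b in graph.edges:
        if a in seeds and b in seeds:
            sub.add_edge(a, b)
    isolated = {s for s in seeds if sub.degree(s) == 0}
    if expand_neighbors:
        for seed in seeds:
            for neighbor in graph.neighbors(seed):
                sub.add_edge(seed, neighbor)
    return GoSubnetwork(
        go_id=go_id,
        seeds=seeds,
        isolated_seeds=isolated,
        graph=sub,
        expanded=expand_neighbors,
    )


def component_origin(
    presence: Mapping[str, set[str]], stages: StageMap
) -> dict[str, str]:
    """Earliest evolutionary stage among the organisms each entity occurs in.

    P if present in any primitive organism, else B if in any bilaterian,
    else V.
    """
    origins: dict[str, str] = {}
    for entity, organisms in presence.items():
        if not organisms:
            raise UsageError(f"entity {entity!r} has empty organism presence")
        try:
            origins[entity] = min(
                (stages[o] for o in organisms), key=_STAGE_ORDER.__getitem__
            )
        except KeyError as exc:
            raise UsageError(f"organism {exc.args[0]!r} missing from stage map")
    return origins


def interaction_evo_group(
    origin_a: str, origin_b: str, origin_edge: str
) -> tuple[str, str]:
    """Evo-group label and complete origin of one interaction.

    The label is the ordered triple (protein A, protein B, edge); the
    complete origin is the latest stage among the three under P < B < V.
    """
    for origin in (origin_a, origin_b, origin_edge):
        if origin not in _STAGE_ORDER:
            raise UsageError(f"unknown origin stage {origin!r}")
    label = origin_a + origin_b + origin_edge
    complete = max(
        (origin_a, origin_b, origin_edge), key=_STAGE_ORDER.__getitem__
    )
    return label, complete


@dataclass
class OriginAnalysis:
    """Origins of every node, edge, and complete interaction of a network."""

    node_origins: dict[str, str]
    edge_origins: dict[tuple[str, str], str]
    evo_groups: dict[tuple[str, str], str] = field(default_factory=dict)
    complete_origins: dict[tuple[str, str], str] = field(default_factory=dict)


def analyze_origins(network, stages: StageMap) -> OriginAnalysis:
    """Classify all nodes and interactions of an integrated network.

    Presence per organism comes from the integration ledgers' source
    organism sets (an edge is present in every organism whose sub-network
    contributed or matched it under the homology renaming).
    """
    node_presence = {name: ledger.sources for name, ledger in network.nodes.items()}
    edge_presence = {pair: ledger.sources for pair, ledger in network.edges.items()}
    node_origins = component_origin(node_presence, stages)
    edge_origins = component_origin(edge_presence, stages)
    analysis = OriginAnalysis(node_origins=node_origins, edge_origins=edge_origins)
    for pair in network.edges:
        a, b = pair
        label, complete = interaction_evo_group(
            node_origins[a], node_origins[b], edge_origins[pair]
        )
        analysis.evo_groups[pair] = label
        analysis.complete_origins[pair] = complete
    return analysis


def pathway_origin_profile(
    graph: nx.Graph,
    members: set[str],
    complete_origins: Mapping[tuple[str, str], str],
) -> dict[str, float]:
    """Per-stage proportions of a pathway's interactions by complete origin.

    Pathway interactions are network edges with both endpoints in the
    member set.  Proportions sum to 1 over stages with at least one
    interaction; a pathway with no interactions yields an empty profile.
    """
    counts: dict[str, int] = {}
    total = 0
    for a, b in graph.edges:
        if a in members and b in members:
            origin = complete_origins[canonical_pair(a, b)]
            counts[origin] = counts.get(origin, 0) + 1
            total += 1
    if total == 0:
        logger.warning("pathway has no interactions among %d members", len(members))
        return {}
    return {stage: counts[stage] / total for stage in STAGES if stage in counts}


def read_pathways(path) -> dict[str, set[str]]:
    """Read a two-column (pathway, protein) TSV into a membership map."""
    table: dict[str, set[str]] = {}
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("pathway\t"):
                continue
            pathway, protein = line.split("\t")[:2]
            table.setdefault(pathway, set()).add(protein)
    return table
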