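"""Iterative sub-network integration with per-turn confidence scoring.

Sub-networks are merged one at a time, closest relative first.  At each
turn the accumulating network is the *target* and the incoming sub-network
the *query*.  Query proteins are matched to target proteins by a
first-passing-BLASTP-hit rule; matched proteins keep the target's name.
Each turn writes one entry into every node's and edge's score ledger:

* edge score R_i — 3 if the (translated) query edge matches an existing
  target edge, 2 for a target edge not matched this turn, 1 for an edge
  newly added from the query; 0 before the edge exists;
* node score A_i / B_i — 2 if the protein absorbed a query homolog that
  shares at least one unigene with it, 1 if it absorbed a homolog with a
  disjoint unigene set, 0 otherwise.

The confidence score of an interaction is S = Σ_{i=1..N} (A_i + R_i + B_i)
over the N integration turns; with N = 5 the maximum is 5 × (2 + 3 + 2)
= 35.  An edge present from the first turn and never matched again scores
at least 2 per turn, so high S marks interactions conserved across many
organisms.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import UsageError
from .homology import EVALUE_MAX_DEFAULT, SubNetwork, best_hits
from .io_formats import HomologyHit, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class NodeLedger:
    name: str
    sources: set[str] = field(default_factory=set)
    unigenes: set[str] = field(default_factory=set)
    per_turn: list[int] = field(default_factory=list)  # values in {0,1,2}


@dataclass
class EdgeLedger:
    pair: tuple[str, str]
    sources: set[str] = field(default_factory=set)
    per_turn: list[int] = field(default_factory=list)  # values in {0,1,2,3}


@dataclass
class TurnRecord:
    turn: int
    query_organism: str
    n_nodes: int
    n_edges: int
    mapping: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other) -> bool:  # mapping is provenance, not state
        if not isinstance(other, TurnRecord):
            return NotImplemented
        return (self.turn, self.query_organism, self.n_nodes, self.n_edges) == (
            other.turn, other.query_organism, other.n_nodes, other.n_edges,
        )


class IntegratedNetwork:
    """Undirected PPI network whose nodes and edges carry score ledgers."""

    def __init__(self, n_turns: int):
        self.n_turns = n_turns
        self.nodes: dict[str, NodeLedger] = {}
        self.edges: dict[tuple[str, str], EdgeLedger] = {}
        self.turn_log: list[TurnRecord] = []

    @classmethod
    def from_subnetwork(cls, sub: SubNetwork, n_turns: int) -> "IntegratedNetwork":
        net = cls(n_turns)
        for name in sub.nodes:
            net.nodes[name] = NodeLedger(
                name=name,
                sources={sub.organism},
                unigenes=set(sub.protein_to_unigenes.get(name, set())),
                per_turn=[0] * n_turns,
            )
        for pair in sub.edges:
            net.edges[pair] = EdgeLedger(
                pair=pair, sources={sub.organism}, per_turn=[0] * n_turns
            )
        return net

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def score(self, pair: tuple[str, str]) -> int:
        pair = canonical_pair(*pair)
        edge = self.edges[pair]
        return score_interaction(edge, self.nodes[pair[0]], self.nodes[pair[1]])

    def scores(self) -> dict[tuple[str, str], int]:
        return {pair: self.score(pair) for pair in self.edges}

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntegratedNetwork):
            return NotImplemented
        return (
            self.n_turns == other.n_turns
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.turn_log == other.turn_log
        )


def match_proteins(
    target: IntegratedNetwork,
    query: SubNetwork,
    hits: Iterable[HomologyHit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
) -> dict[str, str]:
    """Map each query protein to its first passing hit among target nodes.

    Same selection rule as unigene best hits.  The mapping may be
    many-to-one: two query proteins may both collapse into one target
    protein; no injectivity is enforced (collapses are logged).
    """
    relevant = (h for h in hits if h.query in query.nodes)
    mapping = best_hits(relevant, evalue_max, restrict_subjects=set(target.nodes))
    targets = list(mapping.values())
    n_collapsed = len(targets) - len(set(targets))
    if n_collapsed:
        logger.info(
            "%s -> target: %d query proteins collapse onto shared target proteins",
            query.organism, n_collapsed,
        )
    return mapping


def merge_turn(
    target: IntegratedNetwork,
    query: SubNetwork,
    mapping: Mapping[str, str],
    turn_index: int,
) -> IntegratedNetwork:
    """Merge one query sub-network into the target (in place).

    Query edges are translated through ``mapping`` (unmapped endpoints
    keep their query names and are added as new nodes).  A translated
    edge that already existed before this turn is *matched* (R = 3);
    otherwise it is added as new (R = 1).  Pre-existing target edges not
    matched this turn receive R = 2.  A target node that absorbs a query
    homolog scores 2 if the two proteins share a unigene, else 1; all
    other nodes score 0 this turn.
    """
    if not 1 <= turn_index <= target.n_turns:
        raise UsageError(
            f"turn_index {turn_index} outside 1..{target.n_turns}"
        )
    t = turn_index - 1
    preexisting = set(target.edges)

    # --- node merging and point-matching scores -------------------------
    merged: dict[str, list[str]] = {}
    for q_protein, t_protein in mapping.items():
        if q_protein in query.nodes and t_protein in target.nodes:
            merged.setdefault(t_protein, []).append(q_protein)
    for t_protein, q_proteins in merged.items():
        ledger = target.nodes[t_protein]
        q_unigenes = [
            set(query.protein_to_unigenes.get(q, set())) for q in q_proteins
        ]
        shared = any(ledger.unigenes & u for u in q_unigenes)
        ledger.per_turn[t] = 2 if shared else 1
        for u in q_unigenes:
            ledger.unigenes |= u
        ledger.sources.add(query.organism)

    # --- edge translation -----------------------------------------------
    def ensure_node(name: str) -> None:
        if name not in target.nodes:
            target.nodes[name] = NodeLedger(
                name=name,
                sources={query.organism},
                unigenes=set(query.protein_to_unigenes.get(name, set())),
                per_turn=[0] * target.n_turns,
            )

    for a, b in query.edges:
        ta = mapping.get(a, a)
        tb = mapping.get(b, b)
        pair = canonical_pair(ta, tb)
        if pair in preexisting:
            ledger = target.edges[pair]
            ledger.per_turn[t] = 3
            ledger.sources.add(query.organism)
        elif pair in target.edges:  # duplicate translation within this turn
            target.edges[pair].sources.add(query.organism)
        else:
            ensure_node(pair[0])
            ensure_node(pair[1])
            ledger = EdgeLedger(
                pair=pair, sources={query.organism}, per_turn=[0] * target.n_turns
            )
            ledger.per_turn[t] = 1
            target.edges[pair] = ledger

    for pair in preexisting:
        ledger = target.edges[pair]
        if ledger.per_turn[t] == 0:
            ledger.per_turn[t] = 2

    target.turn_log.append(
        TurnRecord(
            turn=turn_index,
            query_organism=query.organism,
            n_nodes=len(target.nodes),
            n_edges=len(target.edges),
            mapping=dict(mapping),
        )
    )
    return target


def integrate_all(
    subnetworks: Sequence[SubNetwork],
    hit_tables: Mapping[tuple[str, str], Iterable[HomologyHit]],
    evalue_max: float = EVALUE_MAX_DEFAULT,
) -> IntegratedNetwork:
    """Integrate sub-networks in the given order.

    ``hit_tables`` maps (query organism, target organism) to BLASTP-style
    hits.  At turn k the query organism's hit tables against every
    already-integrated organism are concatenated (earliest organism
    first) and restricted to the current node names, so matches prefer
    the closest relative already in the network.  N = len(subnetworks) - 1
    turns are executed.
    """
    if len(subnetworks) < 2:
        raise UsageError("integration needs at least two sub-networks")
    n_turns = len(subnetworks) - 1
    network = IntegratedNetwork.from_subnetwork(subnetworks[0], n_turns)
    integrated = [subnetworks[0].organism]
    for turn, query in enumerate(subnetworks[1:], start=1):
        hits: list[HomologyHit] = []
        for target_org in integrated:
            hits.extend(hit_tables.get((query.organism, target_org), []))
        mapping = match_proteins(network, query, hits, evalue_max)
        merge_turn(network, query, mapping, turn)
        integrated.append(query.organism)
        logger.info(
            "turn %d (%s): %d nodes, %d edges",
            turn, query.organism, len(network.nodes), len(network.edges),
        )
    return network


def score_interaction(
    edge: EdgeLedger, node_a: NodeLedger, node_b: NodeLedger
) -> int:
    """S = Σ_{i=1..N} (A_i + R_i + B_i) for one interaction pair."""
    if not (len(edge.per_turn) == len(node_a.per_turn) == len(node_b.per_turn)):
        raise UsageError("ledger length mismatch")
    return sum(edge.per_turn) + sum(node_a.per_turn) + sum(node_b.per_turn)


def score_distribution(
    network: IntegratedNetwork, bin_width: int = 5
) -> list[dict]:
    """Histogram of interaction scores in bins [1..w], [w+1..2w], ...

    Returns one dict per bin with ``low``, ``high``, ``count`` and
    ``percent``; percentages sum to 100 over all edges.
    """
    scores = list(network.scores().values())
    n = len(scores)
    if n == 0:
        return []
    top = max(scores)
    bins = []
    low = 1
    while low <= top:
        high = low + bin_width - 1
        count = sum(1 for s in scores if low <= s <= high)
        bins.append(
            {"low": low, "high": high, "count": count, "percent": 100.0 * count / n}
        )
        low = high + 1
    return bins


def filter_by_score(
    network: IntegratedNetwork, min_score: int
) -> IntegratedNetwork:
    """Keep edges with S >= min_score; restrict nodes to kept edges."""
    kept = IntegratedNetwork(network.n_turns)
    for pair, ledger in network.edges.items():
        if network.score(pair) >= min_score:
            kept.edges[pair] = copy.deepcopy(ledger)
    node_names = {name for pair in kept.edges for name in pair}
    for name in node_names:
        kept.nodes[name] = copy.deepcopy(network.nodes[name])
    kept.turn_log = copy.deepcopy(network.turn_log)
    return kept
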