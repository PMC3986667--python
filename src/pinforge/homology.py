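"""Best-hit selection and model-organism sub-network construction.

A sub-network keeps exactly those interactions of a model organism whose
two partner proteins both have a homologous transcript (unigene) in the
target organism — the interolog filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import HomologyHit, InteractionRecord, canonical_pair

EVALUE_MAX_DEFAULT = 1e-5


@dataclass
class SubNetwork:
    """One organism's interolog-filtered interaction sub-network."""

    organism: str
    stage: str  # P, B or V
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    protein_to_unigenes: dict[str, set[str]] = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def best_hits(
    hits: Iterable[HomologyHit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
    restrict_subjects: set[str] | None = None,
) -> dict[str, str]:
    """Select the first passing hit per query.

    The selection rule is "first aligned sequence with E-value strictly
    below the threshold": the hit with the lowest per-query file rank
    wins.  Ties on rank (possible when hit files are concatenated) break
    by lower E-value, then higher bitscore, then lexicographic subject,
    so the result is deterministic on any input ordering.  Queries with
    no passing hit are absent from the map.
    """
    chosen: dict[str, HomologyHit] = {}
    for hit in hits:
        if hit.evalue >= evalue_max:
            continue
        if restrict_subjects is not None and hit.subject not in restrict_subjects:
            continue
        incumbent = chosen.get(hit.query)
        if incumbent is None or _hit_key(hit) < _hit_key(incumbent):
            chosen[hit.query] = hit
    return {query: hit.subject for query, hit in chosen.items()}


def _hit_key(hit: HomologyHit) -> tuple:
    return (hit.rank, hit.evalue, -hit.bitscore, hit.subject)


def map_unigenes(best: Mapping[str, str]) -> dict[str, set[str]]:
    """Invert a unigene -> protein best-hit map into protein -> unigenes.

    Unigenes and proteins are not one-to-one: several transcripts can hit
    the same protein, so the inverse is a multimap.
    """
    inverted: dict[str, set[str]] = {}
    for unigene, protein in best.items():
        inverted.setdefault(protein, set()).add(unigene)
    return inverted


def build_subnetwork(
    records: Iterable[InteractionRecord],
    protein_to_unigenes: Mapping[str, set[str]],
    organism: str,
    stage: str = "",
) -> SubNetwork:
    """Keep interactions whose both endpoints map to at least one unigene.

    Nodes are the endpoints of kept edges; proteins that map to unigenes
    but take part in no kept interaction are excluded.
    """
    sub = SubNetwork(organism=organism, stage=stage)
    for record in records:
        a, b = record.protein_a, record.protein_b
        if protein_to_unigenes.get(a) and protein_to_unigenes.get(b):
            sub.edges.add(canonical_pair(a, b))
            sub.nodes.update((a, b))
    sub.protein_to_unigenes = {
        p: set(protein_to_unigenes[p]) for p in sub.nodes
    }
    return sub


def subnetwork_summary(
    sub: SubNetwork,
    n_input_interactions: int | None = None,
    n_input_proteins: int | None = None,
    n_total_unigenes: int | None = None,
) -> dict:
    """Counts of unigenes, proteins and interactions in a sub-network.

    Raw counts always; ratios against the supplied input totals where
    those totals are given (they live outside the sub-network itself).
    """
    unigenes = set().union(*sub.protein_to_unigenes.values()) if sub.protein_to_unigenes else set()
    summary: dict = {
        "organism": sub.organism,
        "n_unigenes": len(unigenes),
        "n_proteins": len(sub.nodes),
        "n_interactions": len(sub.edges),
    }
    if n_total_unigenes:
        summary["unigene_fraction"] = len(unigenes) / n_total_unigenes
    if n_input_proteins:
        summary["protein_fraction"] = len(sub.nodes) / n_input_proteins
    if n_input_interactions:
        summary["interaction_fraction"] = len(sub.edges) / n_input_interactions
    return summary
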