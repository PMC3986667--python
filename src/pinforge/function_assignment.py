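"""Neighbor-majority GO assignment for unclassified proteins.

A protein with no biological-process annotation inherits a GO term when
the term is carried by strictly more than a threshold fraction (default
25%) of its annotated neighbors; a protein whose only annotated neighbor
is unique inherits all of that neighbor's terms.  Rounds are synchronous
— every assignment in a round is computed from the previous round's
classified state — and iterate to a fixpoint, so newly classified
proteins can seed further assignments.  No cap is placed on the number
of terms a protein may receive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import UsageError
from .io_formats import AnnotationTable, GoDag


@dataclass
class AssignmentResult:
    assigned: dict[str, set[str]]
    rounds: int
    provenance: dict[str, dict[str, float]] = field(default_factory=dict)


def assign_functions(
    graph: nx.Graph,
    annotations: AnnotationTable,
    threshold: float = 0.25,
    denominator: str = "annotated",
    single_neighbor_rule: bool = True,
) -> AssignmentResult:
    """Iteratively assign GO terms to unclassified proteins.

    ``denominator`` selects what the supporting-neighbor fraction is
    measured against: ``"annotated"`` (neighbors that carry any GO term,
    the default) or ``"all"`` (every neighbor).  Support must be strictly
    greater than ``threshold``.  ``rounds`` counts productive rounds; the
    final empty round that confirms the fixpoint is not counted.
    """
    if not 0 < threshold < 1:
        raise UsageError(f"threshold {threshold} outside (0, 1)")
    if denominator not in ("annotated", "all"):
        raise UsageError(f"unknown denominator mode {denominator!r}")

    classified: dict[str, set[str]] = {
        p: set(t) for p, t in annotations.items() if t and p in graph
    }
    unclassified = set(graph.nodes) - set(classified)
    result = AssignmentResult(assigned={}, rounds=0)

    while True:
        new: dict[str, set[str]] = {}
        prov: dict[str, dict[str, float]] = {}
        for protein in unclassified:
            neighbors = set(graph.neighbors(protein)) - {protein}
            annotated = [n for n in neighbors if n in classified]
            if not annotated:
                continue
            if single_neighbor_rule and len(annotated) == 1:
                terms = set(classified[annotated[0]])
                if terms:
                    new[protein] = terms
                    prov[protein] = {t: 1.0 for t in terms}
                continue
            denom = len(annotated) if denominator == "annotated" else len(neighbors)
            counts: Counter[str] = Counter()
            for n in annotated:
                counts.update(classified[n])
            terms = {t for t, c in counts.items() if c / denom > threshold}
            if terms:
                new[protein] = terms
                prov[protein] = {t: counts[t] / denom for t in terms}
        if not new:
            break
        result.rounds += 1
        for protein, terms in new.items():
            result.assigned[protein] = terms
            result.provenance[protein] = prov[protein]
            classified[protein] = set(terms)
        unclassified -= set(new)
    return result


def go_depth(dag: GoDag, term: str) -> int:
    """Depth of a term: shortest is_a path from its namespace root; root = 1."""
    if term not in dag:
        raise UsageError(f"unknown GO term {term}")
    return dag.depth(term)


def depth_distribution(result: AssignmentResult, dag: GoDag) -> dict[int, int]:
    """Count newly assigned (protein, term) pairs per GO depth."""
    counts: dict[int, int] = {}
    for terms in result.assigned.values():
        for term in terms:
            d = go_depth(dag, term)
            counts[d] = counts.get(d, 0) + 1
    return dict(sorted(counts.items()))


@dataclass
class RecoveryMetrics:
    precision: float | None
    recall: float | None
    n_hidden: int
    n_recovered: int


def recovery_evaluation(
    planted: Mapping[str, str],
    hidden: set[str],
    result: AssignmentResult,
) -> RecoveryMetrics:
    """Precision/recall of recovered planted labels on hidden proteins.

    ``planted`` maps protein -> true GO term; ``hidden`` is the set of
    proteins whose annotation was withheld before assignment.  Recall is
    the fraction of hidden proteins whose planted term was assigned;
    precision is the fraction of assigned (hidden protein, term) pairs
    that match the planted term.  Both are None when their denominator
    is empty.
    """
    n_recovered = 0
    n_pairs = 0
    n_correct = 0
    for protein in hidden:
        assigned = result.assigned.get(protein, set())
        truth = planted.get(protein)
        if truth is not None and truth in assigned:
            n_recovered += 1
        n_pairs += len(assigned)
        n_correct += sum(1 for t in assigned if t == truth)
    recall = n_recovered / len(hidden) if hidden else None
    precision = n_correct / n_pairs if n_pairs else None
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        n_hidden=len(hidden),
        n_recovered=n_recovered,
    )
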