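"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (union-find,
dense Floyd-Warshall via scipy, triple-loop neighbor counting, literal
event replay of the integration rules) and shares no code path with the
package modules it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall


def union_find_components(nodes, edges):
    """Connected components by union-find, largest first."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda c: (-len(c), sorted(map(str, c))))


def floyd_warshall_metrics(nodes, edges):
    """(diameter, average path length over connected unordered pairs)."""
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b in edges:
        if a == b:
            continue
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    matrix = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = floyd_warshall(matrix, unweighted=True)
    finite = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dist[i, j]):
                finite.append(dist[i, j])
    if not finite:
        return 0, 0.0
    return int(max(finite)), float(np.mean(finite))


def brute_clustering(nodes, edges, node=None):
    """Triple-loop clustering coefficients; self-loops ignored."""
    adjacency = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adjacency[a].add(b)
            adjacency[b].add(a)

    def cv(v):
        nbrs = sorted(adjacency[v])
        k = len(nbrs)
        if k < 2:
            return 0.0
        e = sum(
            1
            for x, y in itertools.combinations(nbrs, 2)
            if y in adjacency[x]
        )
        return 2.0 * e / (k * (k - 1))

    if node is not None:
        return cv(node)
    return {v: cv(v) for v in nodes}


def replay_edge_scores(subnetworks, mappings):
    """Literal replay of the per-turn scoring rules.

    ``mappings[i]`` is the query->target renaming used at turn i+1 (the
    query being ``subnetworks[i+1]``).  Maintains the growing edge and
    node sets and per-turn event lists, then sums S = sum_i(A_i+R_i+B_i)
    for every final edge.  Written as a straight transcription of the
    merge rules, independent of the ledger implementation.
    """
    n_turns = len(subnetworks) - 1

    def canon(a, b):
        return (a, b) if a <= b else (b, a)

    first = subnetworks[0]
    edge_r = {canon(*e): [0] * n_turns for e in first.edges}
    node_a = {v: [0] * n_turns for v in first.nodes}
    node_unigenes = {v: set(first.protein_to_unigenes.get(v, set()))
                     for v in first.nodes}

    for t in range(n_turns):
        query = subnetworks[t + 1]
        mapping = mappings[t]
        existing = set(edge_r)
        # node merges: compare every absorbed query protein's unigenes
        # against the target's pre-turn unigene set
        absorbed = {}
        for q, target in mapping.items():
            if q in query.nodes and target in node_a:
                absorbed.setdefault(target, []).append(q)
        for target, qs in absorbed.items():
            unis = [set(query.protein_to_unigenes.get(q, set())) for q in qs]
            shared = any(node_unigenes[target] & u for u in unis)
            node_a[target][t] = 2 if shared else 1
            for u in unis:
                node_unigenes[target] |= u
        # edges
        for a, b in query.edges:
            ta, tb = mapping.get(a, a), mapping.get(b, b)
            pair = canon(ta, tb)
            for name, orig in ((ta, a), (tb, b)):
                if name not in node_a:
                    node_a[name] = [0] * n_turns
                    node_unigenes[name] = set(
                        query.protein_to_unigenes.get(orig, set())
                    )
            if pair in existing:
                edge_r[pair][t] = 3
            elif pair not in edge_r:
                scores = [0] * n_turns
                scores[t] = 1
                edge_r[pair] = scores
        for pair in existing:
            if edge_r[pair][t] == 0:
                edge_r[pair][t] = 2

    return {
        pair: sum(r) + sum(node_a[pair[0]]) + sum(node_a[pair[1]])
        for pair, r in edge_r.items()
    }


def tally_assignment(adjacency, annotations, threshold=0.25):
    """Per-round synchronous neighbor-majority assignment, brute force."""
    classified = {p: set(t) for p, t in annotations.items()
                  if t and p in adjacency}
    assigned = {}
    rounds = 0
    while True:
        new = {}
        for v in adjacency:
            if v in classified:
                continue
            nbrs = [n for n in adjacency[v] if n != v]
            known = [n for n in nbrs if n in classified]
            if not known:
                continue
            if len(known) == 1:
                terms = set(classified[known[0]])
            else:
                counts = {}
                for n in known:
                    for t in classified[n]:
                        counts[t] = counts.get(t, 0) + 1
                terms = {t for t, c in counts.items()
                         if c / len(known) > threshold}
            if terms:
                new[v] = terms
        if not new:
            break
        rounds += 1
        for v, terms in new.items():
            classified[v] = terms
            assigned[v] = terms
    return assigned, rounds
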