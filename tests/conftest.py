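import pytest

from pinforge import synthetic
from pinforge.homology import SubNetwork
from pinforge.io_formats import HomologyHit


@pytest.fixture
def universe_factory():
    def make(seed=1, **overrides):
        config = synthetic.UniverseConfig(seed=seed, **overrides)
        return synthetic.generate_universe(config)

    return make


@pytest.fixture
def universe(universe_factory):
    return universe_factory(seed=1)


def make_subnetwork(organism, edges, unigenes, stage=""):
    """Small helper to hand-build a sub-network from literal tables."""
    sub = SubNetwork(organism=organism, stage=stage)
    for a, b in edges:
        sub.edges.add((a, b) if a <= b else (b, a))
        sub.nodes.update((a, b))
    sub.protein_to_unigenes = {
        p: set(unigenes.get(p, set())) for p in sub.nodes
    }
    return sub


def hit(query, subject, evalue=1e-30, bitscore=200.0, rank=0):
    return HomologyHit(query=query, subject=subject, evalue=evalue,
                       bitscore=bitscore, rank=rank)


@pytest.fixture
def fig_merge_scenario():
    """The canonical merge scenario: target C-D, D-E; query c-d, d-g.

    c and d are homologous to C and D; g is unmatched.  After one turn
    C-D is matched (edge score 3), D-E is target-only (2) and D-g is
    newly added from the query (1).
    """
    target = make_subnetwork(
        "T", [("C", "D"), ("D", "E")],
        {"C": {"U1"}, "D": {"U2"}, "E": {"U3"}},
    )
    query = make_subnetwork(
        "Q", [("c", "d"), ("d", "g")],
        {"c": {"U1"}, "d": {"U2"}, "g": {"U4"}},
    )
    hits = [hit("c", "C", rank=0), hit("d", "D", rank=0)]
    return target, query, hits


@pytest.fixture
def worked_node_score_scenario():
    """Two-organism fixture for the CG6843/CIR-1 worked example.

    Target protein CG6843 and query protein CIR-1 are BLASTP homologs
    and both best-hit the same unigene Unigene6670_A0A, so the merged
    node scores 2 in turn 1.
    """
    target = make_subnetwork(
        "Dmel", [("CG6843", "CG1100")],
        {"CG6843": {"Unigene6670_A0A"}, "CG1100": {"Unigene0001_A0A"}},
    )
    query = make_subnetwork(
        "Cele", [("CIR-1", "W01A-1")],
        {"CIR-1": {"Unigene6670_A0A"}, "W01A-1": {"Unigene0002_A0A"}},
    )
    hits = [hit("CIR-1", "CG6843")]
    return target, query, hits


@pytest.fixture
def conserved_chain_subnetworks():
    """Six one-edge sub-networks sharing one fully conserved interaction.

    Every organism carries the same family edge X-Y with the same two
    unigenes, so across the five integration turns the edge is matched
    every turn and both endpoints undergo same-unigene merges: the
    score ledger attains the theoretical maximum.
    """
    organisms = ["O1", "O2", "O3", "O4", "O5", "O6"]
    subnets = []
    for org in organisms:
        subnets.append(
            make_subnetwork(
                org, [(f"X_{org}", f"Y_{org}")],
                {f"X_{org}": {"UX"}, f"Y_{org}": {"UY"}},
            )
        )
    hit_tables = {}
    for q in organisms:
        for t in organisms:
            if q != t:
                hit_tables[(q, t)] = [
                    hit(f"X_{q}", f"X_{t}"),
                    hit(f"Y_{q}", f"Y_{t}"),
                ]
    return subnets, hit_tables
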