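"""Iterative network integration and per-turn confidence scoring."""

import pytest

from pinforge.errors import UsageError
from pinforge.integration import (
    IntegratedNetwork,
    filter_by_score,
    integrate_all,
    match_proteins,
    merge_turn,
    score_distribution,
    score_interaction,
)
from pinforge.synthetic import build_subnetworks

from conftest import hit, make_subnetwork
from oracles import replay_edge_scores


class TestMatchProteins:
    def test_query_protein_maps_to_first_passing_target_hit(
        self, worked_node_score_scenario
    ):
        target_sub, query, hits = worked_node_score_scenario
        target = IntegratedNetwork.from_subnetwork(target_sub, 1)
        mapping = match_proteins(target, query, hits)
        assert mapping == {"CIR-1": "CG6843"}

    def test_no_passing_hits_gives_empty_map(self, fig_merge_scenario):
        target_sub, query, _ = fig_merge_scenario
        target = IntegratedNetwork.from_subnetwork(target_sub, 1)
        hits = [hit("c", "C", evalue=0.1)]
        assert match_proteins(target, query, hits) == {}

    def test_hits_to_absent_targets_are_ignored(self, fig_merge_scenario):
        target_sub, query, _ = fig_merge_scenario
        target = IntegratedNetwork.from_subnetwork(target_sub, 1)
        hits = [hit("c", "ZZZ", rank=0), hit("c", "C", rank=1)]
        assert match_proteins(target, query, hits) == {"c": "C"}

    @pytest.mark.parametrize("seed", range(1, 4))
    def test_mapping_equals_planted_cross_organism_orthologs(
        self, universe_factory, seed
    ):
        universe = universe_factory(seed=seed)
        subnets, hit_tables = build_subnetworks(universe)
        first, second = subnets[0], subnets[1]
        target = IntegratedNetwork.from_subnetwork(first, 5)
        mapping = match_proteins(
            target, second, hit_tables[(second.organism, first.organism)]
        )
        planted = universe.planted_cross_best[(second.organism, first.organism)]
        expected = {
            q: t for q, t in planted.items()
            if q in second.nodes and t in first.nodes
        }
        assert mapping == expected


class TestMergeTurn:
    def test_matched_target_only_and_new_edge_scores(self, fig_merge_scenario):
        target_sub, query, hits = fig_merge_scenario
        target = IntegratedNetwork.from_subnetwork(target_sub, 1)
        mapping = match_proteins(target, query, hits)
        merge_turn(target, query, mapping, 1)
        assert target.edges[("C", "D")].per_turn == [3]   # matched
        assert target.edges[("D", "E")].per_turn == [2]   # target-only
        assert target.edges[("D", "g")].per_turn == [1]   # added from query

    def test_unmapped_query_edge_added_verbatim(self):
        target = IntegratedNetwork.from_subnetwork(
            make_subnetwork("T", [("A", "B")], {"A": {"U1"}, "B": {"U2"}}), 1
        )
        query = make_subnetwork("Q", [("x", "y")], {"x": {"U5"}, "y": {"U6"}})
        merge_turn(target, query, {}, 1)
        assert ("x", "y") in target.edges
        assert target.edges[("x", "y")].per_turn == [1]
        assert target.nodes["x"].unigenes == {"U5"}

    def test_same_unigene_merge_scores_two_disjoint_scores_one(self):
        target = IntegratedNetwork.from_subnetwork(
            make_subnetwork("T", [("A", "B")], {"A": {"U1"}, "B": {"U2"}}), 1
        )
        query = make_subnetwork("Q", [("a", "b")], {"a": {"U1"}, "b": {"U9"}})
        merge_turn(target, query, {"a": "A", "b": "B"}, 1)
        assert target.nodes["A"].per_turn == [2]  # shares U1
        assert target.nodes["B"].per_turn == [1]  # disjoint unigenes
        assert target.nodes["B"].unigenes == {"U2", "U9"}

    def test_self_merge_under_identity_is_idempotent(self):
        sub = make_subnetwork(
            "X", [("A", "B"), ("B", "C")],
            {"A": {"U1"}, "B": {"U2"}, "C": {"U3"}},
        )
        target = IntegratedNetwork.from_subnetwork(sub, 1)
        identity = {n: n for n in sub.nodes}
        merge_turn(target, sub, identity, 1)
        assert set(target.edges) == sub.edges
        assert set(target.nodes) == sub.nodes
        assert all(e.per_turn == [3] for e in target.edges.values())
        assert all(n.per_turn == [2] for n in target.nodes.values())

    def test_turn_index_outside_range_rejected(self, fig_merge_scenario):
        target_sub, query, _ = fig_merge_scenario
        target = IntegratedNetwork.from_subnetwork(target_sub, 1)
        with pytest.raises(UsageError):
            merge_turn(target, query, {}, 2)

    def test_many_to_one_collapse_translates_edges(self):
        target = IntegratedNetwork.from_subnetwork(
            make_subnetwork("T", [("A", "B")], {"A": {"U1"}, "B": {"U2"}}), 1
        )
        query = make_subnetwork(
            "Q", [("p", "q"), ("q", "r")],
            {"p": {"U1"}, "q": {"U7"}, "r": {"U8"}},
        )
        # p and q both collapse onto A: p-q becomes a self-loop on A
        merge_turn(target, query, {"p": "A", "q": "A"}, 1)
        assert ("A", "A") in target.edges
        assert ("A", "r") in target.edges


class TestIntegrateAll:
    def test_turn_log_counts_are_non_decreasing(self, universe):
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        assert len(network.turn_log) == len(subnets) - 1
        nodes = [e.n_nodes for e in network.turn_log]
        edges = [e.n_edges for e in network.turn_log]
        assert nodes == sorted(nodes) and edges == sorted(edges)
        assert nodes[0] >= len(subnets[0].nodes)

    def test_two_identical_subnetworks_give_isomorphic_network(self):
        subs = [
            make_subnetwork(org, [("A1", "B1"), ("B1", "C1")],
                            {"A1": {"U1"}, "B1": {"U2"}, "C1": {"U3"}})
            for org in ("O1", "O2")
        ]
        # rename query side so matching must go through homology
        subs[1] = make_subnetwork(
            "O2", [("A2", "B2"), ("B2", "C2")],
            {"A2": {"U1"}, "B2": {"U2"}, "C2": {"U3"}},
        )
        hit_tables = {("O2", "O1"): [
            hit("A2", "A1"), hit("B2", "B1"), hit("C2", "C1"),
        ]}
        network = integrate_all(subs, hit_tables)
        assert set(network.edges) == subs[0].edges
        assert set(network.nodes) == subs[0].nodes

    def test_fewer_than_two_networks_rejected(self, fig_merge_scenario):
        target_sub, _, _ = fig_merge_scenario
        with pytest.raises(UsageError):
            integrate_all([target_sub], {})

    def test_final_edges_equal_translated_union_oracle(self, universe_factory):
        """Every input edge, translated through the per-turn renamings,
        appears in the final network — and nothing else does."""
        for seed in (1, 2, 3):
            universe = universe_factory(seed=seed)
            subnets, hit_tables = build_subnetworks(universe)
            network = integrate_all(subnets, hit_tables)
            expected = {tuple(sorted(e)) for e in subnets[0].edges}
            for entry, query in zip(network.turn_log, subnets[1:]):
                mapping = entry.mapping
                for a, b in query.edges:
                    expected.add(tuple(sorted(
                        (mapping.get(a, a), mapping.get(b, b))
                    )))
            assert set(network.edges) == expected


class TestScoring:
    def test_score_is_sum_of_ledgers(self):
        from pinforge.integration import EdgeLedger, NodeLedger

        edge = EdgeLedger(pair=("A", "B"), per_turn=[2, 3, 1])
        na = NodeLedger(name="A", per_turn=[0, 2, 0])
        nb = NodeLedger(name="B", per_turn=[1, 0, 0])
        assert score_interaction(edge, na, nb) == 9

    def test_ledger_length_mismatch_is_an_error(self):
        from pinforge.integration import EdgeLedger, NodeLedger

        edge = EdgeLedger(pair=("A", "B"), per_turn=[2, 3])
        node = NodeLedger(name="A", per_turn=[0])
        with pytest.raises(UsageError):
            score_interaction(edge, node, node)

    def test_fully_conserved_edge_attains_maximum_35(
        self, conserved_chain_subnetworks
    ):
        subnets, hit_tables = conserved_chain_subnetworks
        network = integrate_all(subnets, hit_tables)
        assert len(network.edges) == 1
        (pair,) = network.edges
        assert network.score(pair) == 35

    def test_edge_added_last_turn_with_unmerged_nodes_scores_one(self):
        subs = [
            make_subnetwork("O1", [("A", "B")], {"A": {"U1"}, "B": {"U2"}}),
            make_subnetwork("O2", [("x", "y")], {"x": {"U8"}, "y": {"U9"}}),
        ]
        network = integrate_all(subs, {})
        assert network.score(("x", "y")) == 1

    @pytest.mark.parametrize("seed", range(1, 4))
    def test_scores_match_event_replay_oracle(self, universe_factory, seed):
        universe = universe_factory(seed=seed)
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        mappings = [entry.mapping for entry in network.turn_log]
        expected = replay_edge_scores(subnets, mappings)
        assert network.scores() == expected
        assert all(1 <= s <= 35 for s in expected.values())

    def test_per_turn_component_bounds(self, universe):
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        for ledger in network.edges.values():
            assert all(v in (0, 1, 2, 3) for v in ledger.per_turn)
        for ledger in network.nodes.values():
            assert all(v in (0, 1, 2) for v in ledger.per_turn)


class TestScoreDistribution:
    def test_single_bin_when_all_scores_equal(self):
        subs = [
            make_subnetwork("O1", [("A", "B")], {"A": {"U1"}, "B": {"U2"}}),
            make_subnetwork("O2", [("x", "y")], {"x": {"U8"}, "y": {"U9"}}),
        ]
        network = integrate_all(subs, {})
        bins = score_distribution(network)
        nonzero = [b for b in bins if b["count"]]
        assert {(b["low"], b["high"]) for b in nonzero} <= {(1, 5)}
        assert sum(b["percent"] for b in bins) == pytest.approx(100.0)

    def test_histogram_equals_direct_tally(self, universe):
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        scores = list(network.scores().values())
        for b in score_distribution(network, bin_width=5):
            expected = sum(1 for s in scores if b["low"] <= s <= b["high"])
            assert b["count"] == expected
        assert sum(b["count"] for b in score_distribution(network)) == len(scores)

    def test_empty_network_gives_empty_histogram(self):
        assert score_distribution(IntegratedNetwork(n_turns=5)) == []


class TestFilterByScore:
    def test_min_score_one_is_identity_on_edges(self, universe):
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        kept = filter_by_score(network, 1)
        assert set(kept.edges) == set(network.edges)

    def test_above_maximum_empties_network(self, universe):
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        kept = filter_by_score(network, 36)
        assert kept.edges == {} and kept.nodes == {}

    def test_kept_count_equals_brute_force(self, universe):
        subnets, hit_tables = build_subnetworks(universe)
        network = integrate_all(subnets, hit_tables)
        cutoff = 12
        kept = filter_by_score(network, cutoff)
        expected = sum(1 for s in network.scores().values() if s >= cutoff)
        assert len(kept.edges) == expected
        assert set(kept.nodes) == {n for pair in kept.edges for n in pair}
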