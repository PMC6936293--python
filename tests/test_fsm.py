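from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actinmachine as am
from actinmachine.fsm import StateSequence


def seq(states, input=None, spacing=10):
    return StateSequence(tuple((spacing * (n + 1), s) for n, s in enumerate(states)), input=input)


class TestEncoding:
    def test_spike_only_on_e5_is_state_1(self):
        trains = [am.SpikeTrain(f"e{i}", ()) for i in range(5)] + [am.SpikeTrain("e5", (40,))]
        assert am.states_from_spikes(trains, 6).states == (1,)

    def test_spike_only_on_e0_is_state_32(self):
        trains = [am.SpikeTrain("e0", (40,))] + [am.SpikeTrain(f"e{i}", ()) for i in range(1, 6)]
        assert am.states_from_spikes(trains, 6).states == (32,)

    def test_decimal_bit_roundtrip_for_all_64_states(self):
        for s in range(64):
            assert am.bits_to_state(am.state_to_bits(s, 6)) == s

    def test_no_spikes_gives_empty_sequence(self):
        trains = [am.SpikeTrain(f"e{i}", ()) for i in range(6)]
        assert am.states_from_spikes(trains, 6).events == ()

    def test_roundtrip_from_known_state_sequence(self):
        # spike trains constructed from a state sequence with spacing > the
        # coincidence window must recover exactly that sequence
        states = [38, 24, 1, 17, 52]
        times = [20 * (n + 1) for n in range(len(states))]
        per_electrode = [[] for _ in range(6)]
        for t, s in zip(times, states):
            for i, bit in enumerate(am.state_to_bits(s, 6)):
                if bit:
                    per_electrode[i].append(t)
        trains = [am.SpikeTrain(f"e{i}", tuple(ts)) for i, ts in enumerate(per_electrode)]
        out = am.states_from_spikes(trains, 6)
        assert out.states == tuple(states)
        assert [t for t, _ in out.events] == times


class TestGraphs:
    def test_edges_from_consecutive_events(self):
        g = am.transition_graph(seq([8, 16, 8]))
        assert set(g.edges) == {(8, 16), (16, 8)}

    def test_single_event_graph_has_no_edges(self):
        g = am.transition_graph(seq([5]))
        assert set(g.nodes) == {5} and not g.edges

    def test_empty_sequence_gives_empty_graph(self):
        g = am.transition_graph(seq([]))
        assert not g.nodes and not g.edges

    def test_repeat_transitions_collapse_with_counts(self):
        g = am.transition_graph(seq([8, 16, 8, 16]))
        assert g[8][16]["count"] == 2 and g[16][8]["count"] == 1

    def test_weight_normalization(self):
        G = am.weighted_global_graph([seq([1, 2], input=1), seq([1, 2, 1, 3], input=2)])
        # from 1: two 1->2, one 1->3
        assert G[1][2]["weight"] == pytest.approx(2 / 3)
        assert G[1][3]["weight"] == pytest.approx(1 / 3)
        assert G[2][1]["weight"] == 1.0

    def test_terminal_node_has_no_outgoing_edges(self):
        G = am.weighted_global_graph([seq([4, 9], input=1)])
        assert G.out_degree(9) == 0

    @given(
        st.lists(
            st.lists(st.integers(1, 15), min_size=1, max_size=12),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_outgoing_weights_sum_to_one(self, state_lists):
        seqs = [seq(states, input=n) for n, states in enumerate(state_lists)]
        G = am.weighted_global_graph(seqs)
        for node in G.nodes:
            if G.out_degree(node):
                assert sum(d["weight"] for _, _, d in G.out_edges(node, data=True)) == pytest.approx(1.0, abs=1e-12)
        pruned = am.prune(G)
        assert all(pruned.graph.out_degree(n) <= 1 for n in pruned.graph.nodes)


class TestPrune:
    def test_keeps_max_weight_edge(self):
        G = am.weighted_global_graph([seq([1, 2], input=0), seq([1, 2], input=1), seq([1, 3], input=2)])
        pruned = am.prune(G)
        assert list(pruned.graph.successors(1)) == [2]

    def test_tie_breaks_to_smallest_successor(self):
        G = am.weighted_global_graph([seq([1, 2], input=0), seq([1, 3], input=1)])
        pruned = am.prune(G)
        assert list(pruned.graph.successors(1)) == [2]

    def test_node_classes(self):
        # 5 -> 1 -> 1 (self-loop): 5 has no predecessors, 1 is a fixed point
        G = am.weighted_global_graph([seq([5, 1, 1], input=0)])
        pruned = am.prune(G)
        assert pruned.node_class[5] == "garden_of_eden"
        assert pruned.node_class[1] == "fixed_point"
        assert pruned.indegree[1] == 2  # from 5 and from itself

    def test_terminal_with_predecessors_is_fixed_point(self):
        G = am.weighted_global_graph([seq([5, 1], input=0)])
        assert am.prune(G).node_class[1] == "fixed_point"


class TestRichness:
    def test_single_shared_state(self):
        r = am.richness([seq([8], input=i) for i in (1, 2, 3)])
        assert r.mu(1) == 1
        assert r.table.loc[0, "states"] == (8,)

    def test_distinct_first_states(self):
        r = am.richness([seq([8], input=1), seq([16], input=2)])
        assert r.mu(1) == 2 and set(r.table.loc[0, "states"]) == {8, 16}

    def test_steps_without_events_are_absent(self):
        r = am.richness([seq([8, 16], input=1), seq([9], input=2)])
        assert list(r.table["t"]) == [1, 2]
        assert r.mu(2) == 1  # only input 1 has a second event

    def test_per_input_and_per_state_distributions(self):
        r = am.richness([seq([8, 16, 8], input=3), seq([16], input=5)])
        assert r.per_input == {3: 2, 5: 1}
        assert r.per_state == {8: 1, 16: 2}


class TestGofT:
    def test_indexing(self):
        seqs = [seq([8, 16], input=1), seq([9], input=2)]
        assert am.g_of_t(seqs, 1) == {1: 8, 2: 9}
        assert am.g_of_t(seqs, 2) == {1: 16}

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            am.g_of_t([], 0)


class TestExports:
    def test_dot_output_is_deterministic_text(self):
        from actinmachine.fsm import to_dot

        G = am.weighted_global_graph([seq([5, 1, 1], input=0)])
        pruned = am.prune(G)
        text = to_dot(pruned.graph, pruned.node_class)
        assert text == to_dot(pruned.graph, pruned.node_class)
        assert '"5" -> "1"' in text and "digraph" in text
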