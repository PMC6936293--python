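"""Characterize a droplet network as a finite-state machine.

Each of the 63 non-zero 6-bit input strings is applied as impulses on six
electrodes; the per-electrode spike pattern within each coincidence group
is a machine state (decimal-encoded, electrode 0 = MSB).  Pooling the
state transitions of all inputs gives the weighted global graph G; keeping
each node's heaviest outgoing edge gives the pruned skeleton G*, whose
nodes split into Garden-of-Eden states (no predecessors), fixed points,
and ordinary states.
"""

import actinmachine as am

matrix = am.synth_network(
    am.SynthSpec(kind="delaunay", extent=(64, 64, 8), n_points=40, tube_radius=2.0, seed=7)
)
electrodes = am.auto_electrodes(matrix, 6)
params = am.AutomatonParams(theta=7, delta=20, radius=3)

sequences = []
for decimal in range(1, 64):
    trace = am.run_experiment(
        matrix, electrodes, am.StimulusPattern.from_decimal(decimal, 6), params, steps=300
    )
    trains = am.spike_trains(trace)
    sequences.append(am.states_from_spikes(trains, 6, input=decimal))

G = am.weighted_global_graph(sequences)
pruned = am.prune(G)
rich = am.richness(sequences)

print(f"states observed:      {sorted(G.nodes)}")
print(f"global graph:         {len(G.nodes)} nodes, {G.number_of_edges()} weighted edges")
print(f"garden-of-eden:       {pruned.nodes_of_class('garden_of_eden')}")
print(f"fixed points:         {pruned.nodes_of_class('fixed_point')}")
print("\nrichness (mu(t) = distinct states at transition step t over all inputs):")
print(rich.table.to_string(index=False))
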