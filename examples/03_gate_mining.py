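"""Mine two-input Boolean gates from spike responses of a small network.

Electrodes i and j inject the inputs x and y as impulses; the potential
at a third electrode k is recorded for the input pairs (0,1), (1,0) and
(1,1).  Spikes aligned across the three runs (within the 6-iteration
coincidence window) identify the gate: a spike in all three runs is OR,
only in the joint run AND, only in the two single-input runs XOR, etc.
"""

import actinmachine as am

matrix = am.synth_network(
    am.SynthSpec(kind="delaunay", extent=(48, 48, 8), n_points=24, tube_radius=2.0, seed=3)
)
electrodes = am.auto_electrodes(matrix, 3)

records = am.sweep_params(
    matrix,
    electrodes,
    theta_list=[5, 7],
    delta_list=[20],
    steps=150,
    wiring="all_triples",
)
print(f"{len(records)} gate records over 2 thresholds x 6 ordered input pairs\n")
totals, means = am.aggregate_gate_counts(records, n_outputs=1)
print(totals.to_string(index=False))
print("\nEach row: how often that gate appeared at an output electrode for the")
print("given excitability (theta) and refractory delay (delta); the frequency")
print("profile over theta/delta is what selects the machine's working point.")
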