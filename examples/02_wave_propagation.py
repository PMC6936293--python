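"""Watch an excitation wave travel down a 1-voxel-wide bundle.

With threshold theta=0 and neighbourhood radius r=3 the wavefront
advances exactly 3 voxels per step along an axis, so the far end of a
31-voxel line is first excited at step 10 — a closed-form check of the
automaton update rule.
"""

import numpy as np

import actinmachine as am
from actinmachine.automaton import EXCITED

line = am.synth_network(am.SynthSpec(kind="line", extent=(31, 3, 3), length=31, start=(0, 1, 1)))
params = am.AutomatonParams(theta=0, delta=20, radius=3)

lattice = am.LatticeState.resting(line)
lattice.state[0, 1, 1] = EXCITED

for step_no in range(1, 11):
    lattice = am.step(lattice, line, params)
    front = np.nonzero(lattice.state[:, 1, 1] == EXCITED)[0]
    print(f"t={step_no:2d}  excited x-positions: {front.tolist()}")

print("\nThe front reaches x=30 at t=10: 3 voxels/step, ceil(30/3) steps.")
print("Behind it, voxels are refractory for delta+1 = 21 steps before resting again.")
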