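"""Physical throughput of a droplet machine, back of the envelope.

Travelling localizations in actin bundles move at ~1e5 um/s (the
conservative, action-potential-like estimate; sound solitons would be
faster).  A droplet ~250 um across therefore turns over one input per
signal transit, and a network that stays structurally frozen for 10 s
completes thousands of computation cycles before any remodelling.
"""

import actinmachine as am

est = am.PhysicalEstimate(signal_speed=1e5, machine_size=250.0, stability_window=10.0)
ips, cycles = am.throughput_estimate(est)

print(f"machine states (k=6 electrodes): {am.machine_state_count(6)}")
print(f"parallel inputs per second:      {ips:g}  (~{ips / 1000:.1f} kHz operation)")
print(f"cycles in a {est.stability_window:g} s stable window: {cycles:g}")
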