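# actinmachine

Excitable-medium computing on three-dimensional actin-bundle networks.

Droplets of polymerizing actin self-assemble into stable 3D networks of
filament bundles that conduct travelling excitations (ionic waves,
solitons, conformational defects).  By treating the presence or absence
of an impulse at a site as a logical value, such a network becomes an
unconventional computer.  `actinmachine` is a simulation and analysis
toolkit for this idea, aimed at researchers in unconventional/collision-
based computing and cytoskeleton biophysics:

- **Substrate** — a boolean voxel grid `C` ("conductive matrix") built by
  thresholding RGB confocal stacks (`r > 40, g > 19, b > 19`, strict) or
  synthesized as Delaunay tube networks emulating droplet bundle
  scaffolds, with optional z-compression and a TIFF+JSON container.
- **Dynamics** — a synchronous three-state excitable automaton
  `A = ⟨C, Q, r, h, θ, δ⟩` on the conductive voxels: a resting voxel
  excites iff its count of excited neighbours within Euclidean radius
  `r` strictly exceeds `θ`; an excited voxel turns refractory for `δ+1`
  steps.  Defaults `θ=7, δ=20, r=3`.
- **Interface** — spherical electrodes (strict `d < r_e`, default
  `r_e = 4`, a 251-voxel sphere) inject k-bit input strings as impulses
  and record per-step excited-voxel counts; spikes of these potentials
  represent logical True, with spikes fewer than 6 iterations apart
  treated as simultaneous.  Two laboratory electrode layouts (E1, E2) on
  the 1024×1024×30 confocal network ship as fixtures.
- **Logic mining** — for electrode triples (i, j, k), responses to the
  input pairs (0,1), (1,0), (1,1) classify two-input gates
  (OR, AND, XOR, NOTAND, ANDNOT, SELECT), swept over `θ`/`δ` to find
  the gate-richest working point.
- **Finite-state machine** — per-electrode spike patterns read back as
  k-bit machine states (`M = ⟨A, k, E, S, F⟩`, `|S| = 2^k`, electrode 0
  as MSB); the package builds per-input transition graphs, the weighted
  global graph G (outgoing weights of each node sum to 1), the
  max-weight pruned skeleton G* with garden-of-eden / fixed-point
  classification, richness statistics μ(t), and minimized per-electrode
  Boolean functions in disjunctive normal form (Quine–McCluskey with
  Petrick cover selection, don't-cares for unobserved inputs).

See `docs/methods.md` for the model, conventions and limitations, and
`examples/` for short narrative scripts, one per capability.

## Worked example

Reconstructing and minimizing per-electrode Boolean functions from a
response map `g : inputs → states` at one transition step
(`examples/05_dnf_minimization.py`):

```python
from actinmachine.boolmin import dnf_to_string, minimize_dnf, table_from_g

g = {1: 0b001, 2: 0b011, 3: 0b001, 4: 0b100, 5: 0b101}   # inputs 6, 7 unobserved
for e in range(3):
    print(f"f{e}(x0,x1,x2) = {dnf_to_string(minimize_dnf(table_from_g(g, e, 3)))}")
```

prints

```
f0(x0,x1,x2) = x0
f1(x0,x1,x2) = x1·x̄2
f2(x0,x1,x2) = x1 + x2
```

i.e. electrode 0's response bit equals input bit x0; electrode 1 fires
exactly when x1 is set and x2 is not; electrode 2 fires when x1 or x2
is set — each formula verified against its truth table on every
specified row, with the unobserved inputs 6 and 7 used as don't-cares.

The physical throughput utility (`examples/06_throughput.py`):

```
machine states (k=6 electrodes): 64
parallel inputs per second:      400  (~0.4 kHz operation)
cycles in a 10 s stable window: 4000
```

— a 250 μm droplet traversed by signals at the conservative 10^5 μm/s
estimate processes 400 input strings per second, and a network that
stays structurally frozen for 10 s completes 4×10^3 computation cycles.

A full machine characterization on a synthetic network is in
`examples/04_state_machine.py`; the same stages are scriptable from the
shell:

```sh
actinmachine synth --kind delaunay --extent 64,64,8 --points 40 --seed 7 --out net.tif
actinmachine simulate --matrix net.tif --electrodes els.csv --input-bits 100000 \
    --theta 7 --delta 20 --steps 300 --out trace.csv
actinmachine estimate
```

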