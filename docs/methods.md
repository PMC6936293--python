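# Methods

## The model

`actinmachine` simulates computation by travelling excitations on a
three-dimensional network of actin filament bundles grown in a droplet.
The substrate is a boolean *conductive matrix* `C`: a voxel grid marking
where bundle material exists.  On `C` runs a synchronous three-state
excitable automaton; spherical electrode domains inject impulses encoding
binary strings and record activity, and the recorded spike patterns are
read back as binary strings — so the device as a whole implements a
mapping `F : {0,1}^k → {0,1}^k` and can be analysed as a finite-state
machine.

### Automaton update rule

Each conductive voxel `p` is resting (∘), excited (⋆) or refractory (∙),
with a counter `h_p` timing refractory decay.  With `σ(p)` the number of
excited voxels within Euclidean distance `r` of `p` (voxel index units,
centre excluded):

- ∘ → ⋆ iff `σ(p) > θ` (strict);
- ⋆ → ∙, setting `h_p = δ`;
- ∙ stays ∙ while `h_p > 0`, decrementing `h_p`; with `h_p = 0` it
  returns to ∘.

Hence a voxel excited at step `t` is refractory for exactly `δ+1` steps
(`t+1 … t+δ+1`) and can be re-excited from `t+δ+2` on.  Positions outside
the grid or off the conductive set carry no state and contribute 0 to
`σ`; there is no wraparound (droplet networks are bounded) and no
spontaneous excitation, so the automaton is fully deterministic and the
empty input is provably silent.  A refractory voxel whose counter reaches
0 first returns to resting and can excite no earlier than the following
step — the update equations are applied exactly as written above.

The implementation updates all voxels at once (a convolution with the
binary radius-`r` ball kernel computes `σ`); its equivalence to a literal
per-voxel application of the rule is asserted in the tests against an
independent dictionary-based reference simulator.

### Parameters

| parameter | meaning | default | units | why |
|---|---|---|---|---|
| `θ` | excitation threshold (strict) | 7 | excited neighbours | working point where the network realizes the most Boolean gates |
| `δ` | refractory delay | 20 | steps | ditto; long tails suppress immediate re-entry |
| `r` | neighbourhood radius | 3 | voxels | 122-voxel Euclidean ball; wavefronts advance 3 voxels/step along an axis |
| `r_e` | electrode radius | 4 | voxels | strict `d < 4` sphere = 251 voxels |
| `T` | run length | 1000 | steps | laboratory-scale recordings; scaled runs use 300 |
| window | coincidence window | 6 | steps | spikes fewer than 6 iterations apart are simultaneous |
| `amp_threshold` | spike amplitude floor | 1 | voxels | potentials are integer counts; any non-zero local peak is an impulse |

### Electrodes and encoding

Stimulation sets every conductive **resting** voxel strictly closer than
`r_e` to the electrode centre to excited, as a single-step impulse at
t=0 (`stim_steps` can lengthen it for sensitivity studies); refractory
voxels are never overridden.  Recording counts excited voxels under the
same strict `d < r_e` criterion — the symmetry is a package choice, made
because nothing in the device description distinguishes the two radii.
The potential is therefore an integer series per electrode; spikes are
its local maxima at or above `amp_threshold` (plateaus spike at their
first step; series boundaries count as descents), merged within the
6-step window keeping the earlier time.  The numerical spike criterion is
a package decision: the underlying device work shows spike trains but
never defines a detector, and with integer counts a non-zero local peak
is the natural minimal definition.

Bit `i` of an input or state string maps to electrode `i`, decimal-encoded
with electrode 0 as the most significant bit (a spike only on electrode
e5 at k=6 is state 1).

### Machine states, graphs, richness

A machine state is the per-electrode spike-presence vector within one
coincidence group, pooled across electrodes by single-linkage on the time
axis (gap < 6 chains events together; consequently a long chain can span
more than 6 steps in total — the linkage rule, not a hard group width, is
the defining property).  "Transition step t" indexes successive non-zero
state events, not raw automaton iterations: at almost every raw iteration
no electrode spikes, so indexing by iteration would make nearly every
state the zero string.

The weighted global graph G pools the transition counts of all inputs;
`w(a,b)` is the a→b count divided by the total count of transitions
leaving `a` (self-transitions included in the normalization).  The pruned
graph G* keeps each node's maximum-weight outgoing edge, ties broken
toward the smallest successor decimal for cross-platform determinism.
Node classes on G*: *garden-of-eden* = no predecessors; *fixed point* =
self-edge or no successor (a node with neither predecessors nor
successors is reported as garden-of-eden).  Richness `μ(t)` is the number
of distinct states over all inputs at transition step t; per-input
distinct-state counts and per-state input counts complete the picture.

### Boolean function reconstruction

At a transition step t (the pipeline picks the step with maximal μ), the
map g(t): input → state restricted to responding inputs defines, per
electrode, a partial Boolean function of the k input bits.  Unobserved
inputs are don't-cares — forcing them to 0 would fabricate data — except
input 0, which is fixed to 0 by quiescence; a strict mode (`absent="zero"`)
is available.  Minimization is Quine–McCluskey: prime implicants by
iterated single-bit merging (don't-cares participate), then cover
selection by iterated essential-prime extraction, row dominance and
column dominance, with Petrick's product on the residual cyclic core.
Among minimal covers, ties break by fewest total literals then
lexicographic rendering.  Every result is verified equivalent to its
table on all specified rows, and the tests cross-check against sympy's
`SOPform` as an independent minimizer (agreement as Boolean functions,
not syntax).

## Synthetic networks

The generator emulates the regularly spaced bundle networks that
self-assemble in droplets: `n_points` uniform points in the grid, the
edges of their 3D Delaunay triangulation, each rasterized as a digital
tube (squared point-to-segment distance ≤ `tube_radius²`, integer-exact
in voxel units).  Default `tube_radius` is 2: at the working threshold
θ=7 a wavefront needs more than 7 excited neighbours within r=3, which a
radius-1 tube (≈5-voxel cross-section) cannot sustain, while a radius-2
tube (≈13-voxel cross-section) propagates reliably — thick bundles are
the physically meaningful regime.  Degenerate fixtures — a 1-voxel line
(wavefront speed exactly 3 voxels/step at θ=0) and a closed diamond ring
(every voxel has exactly two conductive 26-neighbours) — give closed-form
expectations for tests.

The scaled-down machine used by the tests and the acceptance script is a
64×64×8 grid with 40 nodes, 6 auto-placed electrodes (farthest-point
sampling over the generator's nodes, so electrodes sit on bundles),
θ=7, δ=20, T=300, all 63 non-zero inputs.  These sizes keep a full
63-input characterization to a few minutes while preserving every
analysis stage.

What the synthetic generator does **not** emulate: the anisotropic voxel
geometry of confocal stacks (0.22×0.22×4 μm — carried as metadata only,
since all model distances are in voxel units), bundle curvature and
thickness variation, imaging noise, and the dense loop structure of
laboratory networks that sustains minutes-long re-entrant activity.  On
small synthetic scaffolds excitation typically dies after the first
wave passes (fronts annihilate on collision), so state sequences are
short and the transition graphs sparse.  Passing tests therefore validate
the machinery — update rule, interfacing, alignment, graph and DNF
analysis — not any quantitative property of laboratory droplet networks,
whose gate counts, state sets and indegrees depend on the specific imaged
network.  Confocal RGB stacks are supported as input (threshold
r>40, g>19, b>19, strict) when such data is available.

## Numerical and design choices

- **z-compression** of stacks is explicit and configurable (integer
  factor + OR/MAX reducer), default factor 1 — geometry is never altered
  silently; the published 16-slice renderings of a 30-slice stack imply
  some compression but no factor, so both raw and compressed electrode
  z-coordinates are supportable via configuration.
- **Sub-simulation of conductive voxels only**: non-conductive voxels are
  not "resting participants"; behaviourally equivalent since σ counts
  excited voxels and only conductive voxels can excite.
- **Tie-breaks**: plateau spikes at first step; pruning ties to smallest
  successor; DNF ties by term count, literal count, lexicographic string.
- **Determinism**: the automaton has no RNG; the only randomness is the
  synthesis seed, and every artefact (CSV/JSON/DOT/GraphML/TIFF) is
  byte-reproducible — the pipeline manifest records SHA-256 checksums and
  a rerun reproduces them.
- **E2 electrode fixture**: the transcribed coordinate table yields 8
  rows although the machine experiments used six electrodes; all 8 rows
  ship, the configuration selects the k-member subset (default: first
  six labels).  No attempt is made to guess which rows are spurious.

## Known limitations

- Gate-frequency tables and FSM statistics on synthetic networks are not
  comparable number-for-number with those measured on laboratory
  networks; only the analysis pipeline is common.
- Single-linkage coincidence grouping can chain spike bursts into one
  event when activity is dense; lowering the window or raising
  `amp_threshold` mitigates this.
- Petrick cover selection after chart reduction is exact but worst-case
  exponential; at k=6 all observed cases complete in seconds.
- The automaton ignores physical voxel anisotropy; distances are in index
  units on the (possibly compressed) grid.
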