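# Methods

## The model and its assumptions

The package samples trajectories of the reaction–diffusion master equation
(RDME): molecules are point particles on a Cartesian mesh, diffusion is a
jump process between face-adjacent voxels at rate D/h² per face, and
reactions are well-mixed within a voxel. The hierarchical variant keeps
L nested meshes on one cube (level 0 = a single voxel, level l has 2^l
voxels per axis; each voxel has one parent and eight children, found by
integer index arithmetic — nothing is stored). Every molecule carries a
(level, voxel) position, and species are assigned a *finest level* at which
their molecules are born.

Assumptions inherited from the RDME: point particles (no crowding or
excluded volume), well-mixedness within a voxel, exponential waiting times.
Assumptions specific to this implementation:

* **Cubic domain, reflective boundaries.** The source material never states
  the boundary condition; reflection (absent faces simply removed from the
  neighbor list, which lowers the boundary voxels' total jump rate)
  preserves the uniform stationary distribution on the closed domain and
  hence the well-mixed limit. Periodic boundaries are not implemented.
* **3D only.** The 2D branch of the rate-conversion correction is exposed
  in `rates.green_correction` for reference, but the printed source of that
  expression is typographically damaged; the implemented form,
  ln(h/(√π σ))/(2π) − 3/(8π) + C₂, is a reconstruction and is not exercised
  by the simulator or validated by the benchmark suite.

## Rates

Bimolecular channels store a microscopic rate k (volume/time). Per mesh
level the per-pair firing rate is k_meso = (k/h³)/(1 + (k/D)G(h,σ)) with
G(h,σ) = 1/(4πσ) − C₃/(6h), where σ and D are the *sums* of the two
reactants' radii and diffusion constants. Useful identities, all covered by
tests: G(h*,σ) = 0 at h* = (2/3)πC₃σ ≈ 3.1759σ; k_meso·h³ equals k exactly
at h*, decreases toward the diffusion-limited value k/(1 + k/(4πσD)) as the
mesh coarsens, and W(h) = (k/D)G(h,σ) is the relative error of the mean
rebind time. Below h* the conversion degrades (a warning is emitted) and
eventually the denominator turns nonpositive, which is treated as an error.
Zeroth- and first-order rates need no conversion.

Level assignment: a species' finest level is the coarsest level whose width
satisfies k/(1+ε) < k_meso·h³ (strict inequality; boundary equality counts
as failing) for *every* bimolecular channel it participates in; species
with no bimolecular involvement live on level 0. If even the finest level
fails, it is assigned with a logged warning — the shipped benchmarks
operate exactly at this edge (their finest width 1/64 is marginally below
h*, by construction). Default tolerance ε = 0.025.

## The event loop

A next-particle method: every molecule owns tentative events on one global
queue ordered by (time, insertion sequence). Per molecule there is one
diffusion event (none on level 0, where there are no neighbors), one
unimolecular event sampled at birth from Exp(Σk) over its first-order
channels (with the channel drawn proportionally at firing — equivalent to
competing clocks, and never resampled on diffusion), and one bimolecular
event per co-located reactive *pair* per channel. Per-pair clocks make the
total propensity in a voxel k_meso·n_A·n_B, i.e. exactly mass action, which
is what the SSA-equivalence test checks. Zeroth-order channels keep one
pending event each.

Co-location across levels: a pair may react iff the finer molecule's voxel
is contained in the coarser one's (same voxel on the same level as the
degenerate case), and fires at the *coarser* level's k_meso — the choice
that reproduces the correct mean binding time, verified empirically by the
cross-level binding test. After a diffusion jump (uniform over existing
neighbors) the mover's pending pair events are dropped and resampled
against all currently co-located partners; partners are found by scanning
the partner species' live-molecule list with bit-shift ancestry tests,
which is exact and, at the benchmark copy numbers (≲ a few hundred), cheap.

Transfers: each molecule tracks the time since its birth or last transfer.
Immediately after a diffusion event — and only then, so that no pending
reaction events are discarded at other times — it is promoted to its parent
voxel while that clock exceeds t_transfer = (C·h)²/6D, the clock resetting
on each promotion (so multi-level hops are possible in principle but do not
occur in practice). Demotion is never spontaneous: coarse→fine moves happen
only through product placement. Placement rule: each product is born on its
species' finest level, in the reactant voxel itself (equal level), its
ancestor (coarser), or a uniformly drawn descendant (finer); products of
one reaction that target the *same* level share a single drawn voxel —
the co-placement that preserves rebinding statistics. For a cross-level
bimolecular reaction the "reactant voxel" is the coarser molecule's (the
reaction fires as if both occupied it). Default transfer constant C = 20,
a deliberately conservative choice; C = 1 is already sufficient for the
rebinding benchmark, and both values are exercised in the test suite.

## Numerical choices

* One seeded RNG stream drives everything in a trajectory; queue ties are
  broken by insertion order, so a fixed seed reproduces counts and event
  logs bit for bit. Ensemble drivers derive 31-bit child seeds per
  trajectory from a master seed via `numpy.random.SeedSequence`.
* Event times are strictly increasing: if t + Exp(rate) rounds to t (which
  happens in long runs once t is ~10 orders of magnitude above a fine-mesh
  waiting time), the time is bumped by one ulp.
* Removal-by-molecule on the queue is lazy: version stamps invalidate
  events, stale entries are discarded when they surface. The queue view
  exposed to callers filters them out.
* The event loop is compiled (numba); molecule slots are recycled through a
  free list, and all arrays grow geometrically on demand, so memory is set
  by the peak number of concurrent molecules and pending events.
* Sampling convention: a trajectory records counts *after* executing every
  event with firing time ≤ the sample time.
* Degenerate inputs: k = 0 channels schedule nothing; D = 0 species never
  diffuse and never transfer (t_transfer = ∞); an A + A channel pairs
  distinct molecules only.

## Reference solvers and what the tests show

`reference.ssa_run` is an independent Gillespie direct-method implementation
of the well-mixed master equation; its bimolecular propensities use k_meso
at h = V^(1/3) — the same rate the coarsest hierarchy level uses — so a
one-level hierarchical run and the SSA sample the *same* CME (pure
mass-action k/V is available behind a flag). `reference.npm_single_mesh`
pins every species to one level and disables transfers; it is the same
engine code path (flags only) and serves as the fine-mesh reference for
the rebinding and mesh-refinement comparisons.

The benchmark models are generated in code (`fixtures`): a reversible pair
for rebinding statistics, one- and two-layer dissociation–association
chains, and a MAPK cascade, fully parameterized on the unit cube with a
7-level hierarchy. They emulate the regime where hierarchical resolution
matters — diffusion-limited association, products born in contact, slow
species in moderate copy numbers. They do not emulate realistic cell
geometry, crowding, membrane interactions, or meshes finer than h* (where
the RDME itself stops being faithful), so passing tests demonstrate
correctness of the solver against its own model class and its fine-mesh and
well-mixed limits, not agreement with any particular experimental system.

Problem sizes in the statistical tests are chosen to give comfortable power
at short runtimes: 500 trajectories for endpoint moments (3-standard-error
acceptance band), 10⁴ rebind events per distribution sample (two-sample KS
at the 5% level), 10⁴ replicates for the mean-binding-time rule, and 40
trajectories per arm of the mesh-refinement sweep, whose acceptance is the
monotone error trend rather than absolute error values (those depend on the
reference solver used to define them).

## Known limitations

* Partner scanning is linear in the partner species' copy number; systems
  with ≫10³ co-located reactive molecules would want a per-voxel occupancy
  index instead.
* Uniform Cartesian refinement only; no unstructured or spatially adaptive
  meshes, no per-region resolution control, and no 2D/1D domains.
* The molecule-level trajectory sampler reports copy numbers; spatial
  summaries beyond the event/transfer logs (e.g. concentration fields) are
  left to post-processing.
* Molecule ids are recycled after death; event logs identify reactions by
  channel and time, which is what the shipped observables need.
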