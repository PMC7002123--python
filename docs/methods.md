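# Methods

## Model

Agents are disks (2D) or spheres (3D) of diameter BL, the model's only
intrinsic length. Each agent carries a signed speed along its heading and,
in 3D, an independent vertical speed; self-propulsion relaxes the (planar)
speed toward a preferred speed v0 at rate γ. The only interaction is
through the *binary visual projection field*: the indicator function of the
set of retina directions occluded by any other body. Occlusion carries no
depth, so the field of many neighbors is the set union of their individual
projections; a body hidden behind a nearer one contributes nothing.

The movement response is the lowest-order functional of that field
compatible with the symmetries of a left-right symmetric observer: speed
responds to the cos-weighted field (front-back structure), turning to the
sin-weighted field (left-right structure). Each carries two terms:

* an **area** term, −V, integrating the occupied angle against the kernel:
  large silhouettes repel (brake when ahead, turn away when beside);
* an **edge** term, weighted by α1 (speed), β1 (turning), λ1 (vertical),
  that acts on the boundaries of the occupied region and attracts.

Both hooks for responses to the temporal derivative of the field (α2, β2)
exist in `ModelParams` but default to zero and are outside the validated
scope of this package.

### The edge functional of a binary field

(∂φV)² of an indicator function is a squared Dirac delta and has no value
in the continuum. We define the edge functional as a **unit-weight Dirac
comb**: every edge of the occupied region contributes kernel(φ_edge)
exactly once, independent of any discretization. This choice makes the
edge coefficients dimensionless and is the unique normalization consistent
with the closed-form front-back pair equilibrium L_eq = BL/(2α1) in the
far field; the exact balance condition is BL/(2d*) = sin(arctan α1), which
the simulated pair reproduces to a fraction of a percent. Boundaries at
±π created by splitting a wrapping arc are storage artifacts, detected by
continuity across the cut, and are never counted as edges. An agent whose
retina is fully covered has no edges and zero area functionals: its social
response vanishes and it coasts.

### 2D geometry

Arc unions are computed exactly (sorted-endpoint merging on the circle),
so the four functionals A_cos, A_sin, E_cos, E_sin are analytic — there is
no retina discretization in 2D. A brute-force rasterized retina (2·10⁵
bins) serves as an independent oracle in the tests. The production inner
loop is a numba-compiled version of the same interval merge; a pure-numpy
implementation ships alongside it and the two are cross-checked on random
configurations.

### 3D geometry

The 3D retina is a uniform (φ, θ) grid, default 128 × 64, θ cells mirrored
about the horizon so that a z-symmetric scene gives an *exactly* zero
vertical response (the vertical functionals are evaluated as
upper-minus-lower hemisphere sums with bit-identical weights and summation
order; a swarm initialized exactly in a plane therefore stays planar
forever). A neighbor at distance d occupies every cell whose center lies
within arcsin(min(1, BL/2d)) of its direction. Edges are detected along φ
only (periodic, at inter-cell midpoints), each contributing once per θ-row
with the row weighted by cos θ Δθ (planar terms) or sin θ Δθ (vertical
term) — the row-wise analogue of the 2D Dirac comb; up-down edges are
deliberately ignored. The retina is anchored to the world frame rotated
only by the planar heading: agents translate vertically without pitching.

Binary cap rasterization converges only linearly in the grid spacing:
functionals change by a few percent (not <1%) when doubling the default
resolution, with the staircase error oscillating around the limit. The
collective-state results below are insensitive to this; quantitative work
on single-pair 3D responses should use ≥512 × 256 grids.

## Integration and units

Synchronous explicit Euler with dt = 0.05 in units BL = v0 = γ = 1 (time
unit BL/v0); every agent's field is evaluated from the pre-step state,
then speeds/headings update first and positions move with the updated
velocities (for the vertical oscillation this velocity-first ordering is
symplectic, so the undamped z-motion conserves rather than gains energy).
Speed is signed and never clamped — strong frontal repulsion can drive an
agent backwards without flipping its heading. A step that produces a
non-finite value raises an error naming the agent and the offending term.
Halving dt changes trajectories at first order, as expected for Euler;
the collective states reported here are unchanged at dt = 0.01.

## Parameters

| name | meaning | default |
| --- | --- | --- |
| γ | speed relaxation rate (1/time) | 1 |
| v0 | preferred speed (BL/time) | 1 |
| α0, β0, λ0 | response strengths: speed, turning, vertical | 1, 1, 0 |
| α1, β1, λ1 | dimensionless edge-attraction weights | 0.08, 0.08, 0 |
| BL | body diameter (length unit) | 1 |
| dt | Euler time step | 0.05 |
| retina grid | 3D only, φ × θ | 128 × 64 |

α1 sets the emergent pair spacing BL/(2α1); 0.08 puts it at 6.25 BL. The
2D collective-state studies use N = 50 with α1 = β1 = 1/12.5 and the
(α0, β0) pairs of the regimes studied; the 3D flattening study uses
α0 = 5, β0 = 2, λ0 = 10, α1 = β1 = 0.1 and varies λ1 across α1.

## Initial conditions and what the generators emulate

`init_swarm` / `init_swarm_3d` draw positions uniformly in a square box of
side ⌈√N⌉·L_eq (so the group starts near its expected steady density),
headings uniform, speeds at v0; in 3D, z is drawn from a slab of half the
box's quarter-height plus a tiny jitter, since without a symmetry-breaking
bias a perfectly planar group can never leave its plane. These emulate an
unstructured release of real animals into open space; they do not emulate
boundaries, noise, body-size variation, or perceptual latency — so passing
tests show the model's intrinsic ordering behavior, not robustness of real
groups to those factors.

`make_planar_flock` prepares the configuration the 3D flattening study
presupposes: a compact group with a common heading direction (0.1 rad
jitter), z confined to a 0.5 BL slab, settled for 300 time units with the
vertical response switched off (z is frozen exactly during settling
because λ0 = 0 implies dv_z = 0). Two findings motivate it. First, the 3D
visual coupling decays with distance in *both* the area and edge terms, so
a dilute group of randomly oriented spheres disperses before it can
organize — at the flattening-study coefficients even a pair escapes unless
roughly co-aligned, while co-aligned pairs bind robustly at ≈3.5 BL
(close to the analytic front-back estimate πBL/(8α1) ≈ 3.9). Second, the
vertical equation has no relaxation term, hence no vertical dissipation:
vertical kinetic energy acquired during a violent planar transient is
never removed, and a group released with a large z spread can oscillate
but never contract below one BL. The flattening transition is therefore a
statement about the *stability* of the near-planar flock, and the
experiment starts from one.

## Analysis choices

* Post-transient window: second half of a run unless stated.
* Extents: time-averaged instantaneous values (max pairwise distance in
  the xy projection; max z minus min z).
* Polarization: |mean unit velocity|; in 2D the heading vector, in 3D the
  normalized full velocity, so vertical motion degrades planar order.
* Neighbor persistence: fraction of each agent's 3 nearest neighbors
  retained across a 25-time-unit lag, averaged over several lags.
* A collision is a pairwise distance below one BL (bodies overlap).

## Run lengths

The ordered states form slowly when the turning response is weak: the
N = 50 polarized state at (α0, β0) = (0.2, 0.01) needs ≈1.5·10⁴ time
units in the realization shipped in the tests, and formation times vary
strongly across initial conditions (another seed remained disordered past
2.4·10⁴). Disordered states (fluid swarm, crystal-like) equilibrate within
a few hundred time units and are measured over 2200; small groups (N = 10)
order within a few thousand and are measured over 8000; the 3D flattening
runs use 500 time units after settling.

## Known limitations

* The crystal-like regime (α0 = 0.1, β0 = 10) is collision-free with
  min distance ≥ 1 BL and disordered headings, but neighbor identities
  churn slowly (3-NN retention ≈0.2–0.3 per 25 time units, vs ≈0.1 in the
  fluid swarm) rather than locking outright at the durations simulated;
  "locked" is operationalized comparatively, not absolutely.
* With weak vertical attraction (λ1 < α1) a small (N = 10) flock does not
  reach a bounded vertical configuration: the implied vertical spacing
  (≈BL/(2λ1) and beyond) is too dilute for the decaying 3D coupling, and
  the group expands vertically without bound. Larger groups may instead
  settle into a thick bounded slab; that regime was not simulated here.
* Temporal-derivative (optical-flow) responses, graded/contrast fields,
  blind angles, noise and periodic boundaries are out of scope.
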