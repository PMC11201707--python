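# Model and methods

`autopoiesim` simulates a minimal self-producing chemistry in continuous 3D
space: spherical particles in a sealed cubic container, joined by harmonic
bonds into dendritic networks, transformed by six stochastic reaction
mechanisms. The scientific question the tool serves is whether an entity can
maintain its individuality *without* a spatial (topological) boundary —
individuality here is read purely off the bond graph, and "boundaries" arise
only from which metabolic pathways are enabled.

## Particles and environment

Three species inhabit a sealed cube (side 40 length units, reflective
walls):

| species | rC | rI | mass | drag D [1/s] | max bonds | role |
|---|---|---|---|---|---|---|
| alpha | 0.25 | 1 | 1 | 1 | 0 | inert food |
| beta | 0.5 | 2 | 2 | 2 | 2 | chain links |
| gamma | 1 | 3 | 4 | 4 | 4 | catalytic hubs |

Two particles interact when their center distance is at most the sum of
their interaction radii rI; a bond whose endpoints leave that range is
severed. Masses are expressed in alpha-equivalents (beta = 2, gamma = 4),
so the total mass of the closed system is exactly conserved by every
reaction; the standard initial condition (1000 alpha + 2 gamma) carries
1008 mass units.

The solvent is implicit ("ether"): it exerts linear drag −mDv and delivers
Brownian kicks. No explicit solvent particles, hydrodynamics, or rigid-body
rotation are modeled.

## Physics layer

Each of the 50 timesteps per second (dt = 0.02 s) applies, per particle,

F_net = F_R + F_spring + F_torsion + F_collision − m D v,

integrated by semi-implicit Euler (v += dt·F_net/m, then x += dt·v), which
is stable at the default stiffness (K_L = 100) and masses.

* **Random walk.** F_R(t) = c·F_R(t−1) + (1−c)·g, with g zero-mean Gaussian,
  per-axis standard deviation w, c = 0.5, w = 25. The stationary per-axis
  variance of the process is w²(1−c)/(1+c). w is the rate constant setting
  the average particle speed: a free alpha reaches a mean speed of ≈ 4
  length/s and an effective diffusivity of ≈ 6 length²/s, which is what
  lets the food supply reach the growing entities on the 300 s experimental
  timescale. (Treating w as a per-axis *variance* instead would slow alpha
  transport ~25-fold and stretch equilibration beyond any practical run
  length; the std reading is the one consistent with w's stated
  speed-setting role, and it is the package's fixed convention.) New
  particles start with F_R = 0; a particle transformed in place keeps its
  kinematic state.
* **Linear springs.** Each bond is an ideal spring with rest length equal to
  the sum of the two collision radii and stiffness K_L = 100; forces are
  equal and opposite.
* **Torsion springs.** For every unordered pair (A, C) of bound neighbors
  of a center B with at least two bonds, a restoring torque
  τ = K_T·(∠ABC − θ*(N_B)) drives the angle toward the
  coordination-dependent target (2 → 180°, 3 → 120°, 4 → 109.4712°:
  linear, trigonal, tetrahedral). The angle error is taken **in degrees**
  (K_T = 3 per degree) — the scale on which the target table and spring
  constant are quoted; on the radian scale the chains are an order of
  magnitude floppier and the networks measurably less extended. The torque
  is applied as a force of magnitude τ/|lever| perpendicular to each bond
  in the ABC plane, with the recoil −(F_A + F_C) on B, so every triple's
  three forces sum to zero exactly. Collinear triples have no defined
  bending plane and contribute nothing.
* **Collisions.** Overlapping collision spheres repel linearly with
  stiffness K_coll = 200 (config-exposed). Any strong short-range repulsion
  serves; the model's behavior is not sensitive to the exact contact law.

Spring, torsion and collision forces are internal and sum to zero over the
system every step; only drag and the random walk exchange momentum with the
implicit solvent.

## Chemistry layer

Chemistry runs once per timestep, *before* the physics update, on the
neighbor lists left by the previous step. Particles are visited in a fresh
uniform random order; each particle initiates at most one mechanism per
timestep. Eligible mechanisms are rolled in a fixed order with independent
draws — growth and bonding first, decay last (gamma: A, B, F; beta: C, D,
E) — and the first success is applied immediately. Particles consumed
earlier in the same timestep are tombstoned: they can neither initiate nor
serve as reagents, so no particle takes part in two consuming reactions in
one step, and a freed particle slot is never reused within the step that
freed it.

The per-timestep probabilities (never rescaled):

* **A — beta synthesis.** A gamma with ≥ 2 food alphas in range converts
  them to one beta (probability pA1(N) = 1, 0.5, 0.25, 0.125, 0.0625 for
  N = 0..4 bound neighbors; the two nearest alphas are taken, the nearer is
  transformed, the farther destroyed). With probability pA2 = 0.25 — and a
  free bond site — the beta is incorporated (bonded to the gamma at rest
  length, on the transformed alpha's bearing); otherwise it is ejected
  unbonded at the alpha's position. The beta is colored like its catalyst.
* **B — gamma synthesis.** A gamma with ≥ 2 *bound* betas consumes the two
  nearest of them and splits into two bonded daughter gammas (probability
  pB(N) = 0, 0, 1e-3, 4e-3, 16e-3), both colored like the parent, placed
  ±rC/2 along a random axis; surviving neighbors re-bond to the nearer
  daughter with capacity.
* **C — addition** (repair/fusion; pC). A beta with exactly one bond bonds
  a uniformly chosen in-range particle that has a free site.
* **D — free-beta bonding** (capture; pD1, pD2). An unbonded beta picks a
  random in-range beta/gamma target R. With pD2(N_R, species) it simply
  bonds R ("addition"); otherwise it *inserts* itself into the bond
  between R and R's bound neighbor nearest to the beta (one bond severed,
  two formed). pD2 reaches 0 at full coordination, so saturated targets are
  always entered by insertion; a target with no bonds (pD2 = 1) is always
  added to.
* **E / F — decay.** A beta reverts to 2 alphas (pE(N) = 16e-3, 4e-3,
  1e-3), a gamma to 4 alphas (pF(N) = 16e-4 … 1e-4), products jittered by
  0.1 length units; all bonds are severed. Better-connected particles are
  more stable, so interconnection is selected for.

The three experiments differ only in the bonding pathways: I enables both
repair/fusion and capture (pC = 0.04, pD1 = 0.08); II suppresses
repair/fusion (pC = 0); III suppresses both (pC = pD1 = 0), leaving
internal synthesis (A) as the sole path by which an instance acquires
betas.

Color (+1 red / −1 blue) marks provenance only; it never influences any
rate or eligibility. Because gamma color is inherited strictly from parent
gammas, a color lineage that loses its last gamma is extinct forever — the
runner exploits this to abort coexistence-conditioned runs early.

## Instances and observables

An *instance* is a connected component of the bond graph; it is *viable*
(counted) only if it contains at least one gamma, since without a catalyst
a fragment cannot re-produce its members. Alphas never bond and are
environment. Components are found with a sparse connected-components
routine (verified in the tests against union-find and networkx oracles);
identity is per-frame, not tracked through time.

Per sampled second (1 Hz) the package records: viable-instance counts
overall and by majority gamma color (ties excluded), instance-size min /
mean / max, beta / gamma / total mass over instance members, and the mean
color of each species within majority-red and majority-blue instances
(per-instance mean, then unweighted average over instances; a
pooled-particle variant is available behind a flag). Steady-state summaries
are means and population (n-divisor) standard deviations over the final
window, by default the last 60 s.

## Synthetic conditions, problem sizes, and what the tests show

There are no external data: the generator of experimental conditions *is* the
initial-condition routine (1000 alphas + 1 red + 1 blue gamma uniform in
the 40³ cube, at rest, unbonded). All reported experiments run 300 s at 50
steps/s and, by design, condition on both color lineages
surviving (rerun with incremented seed otherwise; attempts are recorded).
The test suite exercises shorter horizons (20–180 s) and smaller boxes for
invariants, and 180 s full-scale runs for the cross-experiment ordering;
the acceptance script runs the full 300 s protocol.

Two pieces of the physics are deliberate modeling choices rather than
derived laws: the soft-sphere contact law and the lever-arm normalization
of the torsion force. These choices leave the conserved quantities, purity invariants and steady-state
masses intact, but the fracture-fusion balance of the fully-enabled schema
(experiment I) sits near a percolation threshold: in this implementation
the experiment-I network fragments into tens of transient instances rather
than one box-spanning collective, so largest-component statistics are
sensitive to the reconstruction even while total mass and gamma fraction
are not.

## Numerical choices and edge cases

* Semi-implicit Euler, dt fixed at 0.02 s; probabilities are per-timestep by
  definition and are never rescaled with dt.
* Neighbor search: k-d tree pair query at the maximal interaction range
  (6.0), filtered per-pair; an O(N²) oracle backs the tests.
* Degenerate geometry (zero-length bond vectors, collinear torsion triples)
  contributes zero force. Positions are clamped to the container after
  reflection; newly created particles are clamped into the box.
* Ties in nearest-particle choices break toward the lower particle id;
  empty observable categories (e.g., no blue-majority instances) are NaN in
  memory and empty fields in CSV.
* Non-finite positions or velocities abort the run with an integration
  error rather than propagating silently.

## Known limitations

* Single-threaded; a 300 s full-scale run takes a few minutes of wall time.
* No cross-frame instance tracking (lineage trees of instances are out of
  scope; only per-frame censuses are produced).
* The degree of experiment-I collectivization is reconstruction-sensitive
  (see above); cross-experiment orderings and purity results are robust.
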