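# Methods

## The model

`musselflow` simulates the dispersal of green-lipped mussel larvae and of
the macroalgae/spat aggregations that carry juveniles after their first
settlement. Particles are passive except for a constant sinking velocity;
the two life stages differ only in their release depths, tracking windows
and settlement rules.

Positions live in a local projected plane (x east, y north, meters), z in
meters positive down, time in seconds from scenario start. Velocity fields
are sampled multilinearly: trilinear in (x, y, z) with constant
extrapolation in the half-cell rim and beyond the deepest level, linear in
time for unsteady fields (steady fields carry a single snapshot). Advection
uses the classical 4th-order Runge–Kutta scheme with a 900 s step; backward
trajectories use the same kernel with a negative signed step, which is
equivalent to reversing the currents.

Each step applies, in order: advection, horizontal random-walk diffusion,
sub-stepped vertical random-walk diffusion, sinking, the boundary rule, and
the settlement check. The ordering is a modelling choice (it applies the
boundary rule once, to the final proposed position); no other ordering is
implied by the physics at this step size.

### Stochastic terms

Unresolved turbulence is a Gaussian random walk: per axis the horizontal
increment has standard deviation sqrt(2 K_h dt) with K_h = 0.1176 m² s⁻¹;
the vertical increment is the sum of dt / 90 s consecutive draws of standard
deviation sqrt(2 K_v · 90 s) with K_v = 0.01 m² s⁻¹. Both are switched off
in backward mode by default — deterministic backtracking excludes the
stochastic terms, since a reversed random walk does not reconstruct origins
— and forcing them on raises a warning.

Randomness is counter-based: a Philox generator keyed on the master seed
with the step index as counter yields, each step, a block of normals indexed
by absolute particle id. Draws for particle i at step k therefore depend
only on (seed, i, k), so trajectories are bit-reproducible and independent
of how a batch is partitioned. This replaces a per-particle generator
stream, which gives the same guarantee but is not tractable vectorised.

### Biology

* Larvae: pelagic larval duration 35 d, competency from 21 d, sinking
  0.001 m s⁻¹ (within the range reported for bivalve larvae).
* Spat (macroalgae rafts): tracked 20–30 d, settlement from 10 d,
  bottom-drifting (released 1 m above the seafloor; in water shallower than
  2 m, mid-column).
* The spat-age lag along the harvesting beach (older animals further north)
  is linear from 0 at the southern end to 5.5 d at the northern end.
  Linearity is a choice; only the endpoints are constrained. The lag
  extends a particle's tracked duration and its density-analysis window,
  not its competency.
* Settlement requires the horizontal position to fall inside a habitat
  polygon while the age is inside the competency window; the first
  containing polygon wins (sites are disjoint; the ordering matters only
  where extracted settlement areas overlap sites, and sites take priority).
* The boundary rule re-applies the previous position whenever a move ends
  on land or below the seafloor ("moved back"); a surface breach clamps
  z to 0. Lateral exits from the model domain remove the particle
  (open-boundary loss). Every particle ends settled, expired or removed.

### Experiments

The four experiment presets (see `experiments.py` for the full table):
backtracking spat from the beach with no settlement targets (trajectory
densities only); backtracking larvae from the primary settlement areas onto
the 18 populations, stopping on first contact; forward tracking from all 49
sites onto sites + primary areas; forward tracking of spat from the primary
areas onto sites. 1000 particles per release point per month, release
instants evenly spaced within each calendar month (midpoints of equal
sub-intervals — "linearly in time" read as even spacing, the reproducible
reading), positions uniform over the release geometry, 200 points (or 20
per site) at full scale.

Primary settlement areas are extracted from the backtracked-trajectory
density: probability of presence on a configurable grid, cells kept where
expected particles per km² (probability × released count / cell area)
reach 0.6, 4-connected labelling, cell-union polygons dilated by 500 m,
buffered components merged when they overlap with positive area (the
earlier label wins). The probability-to-count conversion is a choice made
to restore the stated unit of the threshold; both the threshold and the
count are parameters.

### Connectivity and genetics

Connectivity matrices store settlement fractions with rows = sources,
columns = sinks (local retention on the diagonal). The published analysis
is internally inconsistent about this orientation (the in-text index order
swaps it); rows-as-sources follows its figures and is fixed here. Yearly
matrices are averaged element-wise into the decadal matrix. Secondary
connectivity is the product of the (sites × areas) and (areas × sites)
stage matrices; total = primary + secondary. Dispersal kernels bin
straight-line release-to-settlement distances (along-coast distance is not
used); kernels for matrix products use site-centroid distances, since the
chained two-stage paths have no single release record. The EOF
decomposition is an SVD of mean-removed, flattened yearly matrices.

Down-scaling to populations sums implied settler counts over site groups
before re-fractionalising by group releases, so totals are conserved
(never a mean of fractions). The migration matrix divides each column by
its sum; receiving populations with no settlement remain zero columns and
are flagged degenerate. Generational projection is a plain matrix power:
column-stochasticity is preserved automatically for columns whose mass does
not route through degenerate populations; columns that leak are
renormalised, and columns that collapse entirely are re-flagged degenerate.
In a strongly advective one-way flow most columns eventually drain — an
honest property of such a system, visible in the synthetic scenario.

Nei's D_A is applied to **columns** of the migration matrix (the
source-composition profiles): D_A(i, j) = 1 − Σ_k √(M_ki M_kj), one minus
the Bhattacharyya coefficient. Only the column reading makes the stated
properties exact — symmetric, zero diagonal, bounded in [0, 1] — because
rows of a column-standardised matrix need not sum to one. A row-based
variant is deliberately not offered.

The Mantel test correlates the strict upper triangles (Pearson) and obtains
its p-value from simultaneous row/column permutations of the second matrix:
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), one-tailed for positive
association by default (the isolation-by-resistance hypothesis; a negative
observed correlation then simply yields a large p). 5000 permutations by
default. The permutation scheme and tail are this package's choices; the
original analysis does not specify them.

## The synthetic ocean

The synthetic scenario emulates the statistical structure of the
north-western New Zealand shelf rather than its bathymetry or forcing: a
600 × 100 km domain at 5 km resolution, 4 depth levels (0, 10, 30, 60 m)
with linear vertical interpolation and a linear attenuation of horizontal
speed to 70% at the deepest level, a straight meridional coast, and a
bathymetry deepening linearly offshore (5 m at the coast, 2 m per km,
capped at 150 m).

The horizontal flow is derived from a discrete streamfunction sampled at
cell centres and differenced centrally, which makes the centred-difference
divergence vanish identically — the property the trajectory kernel relies
on. Three analytic ingredients:

* opposed alongshore jets merged with a tanh profile across the
  convergence latitude: the inshore band (e-folding width 10 km, peak
  0.05 m s⁻¹) flows north south of the convergence and south north of it,
  with the convergence exporting water offshore;
* a southward offshore Gaussian jet (peak 0.10 m s⁻¹, 40 km offshore,
  15 km wide) — the southward shelf current analogue;
* Gaussian streamfunction eddies: one offshore of the bay near the
  harvesting beach, and one retention eddy beside each habitat block.
  The block eddies (800 m² s⁻¹, 8 km radius, centred 10 km offshore)
  close recirculation cells over the site band, producing the local
  retention and bidirectional alongshore exchange the regional analysis
  reports; without them a purely one-way conveyor has no self-recruitment
  and its migration matrix drains to zero under generational projection.

The habitat is 49 square 5 × 5 km sites hugging the coast in 18 contiguous
populations: a southern block (8 populations), the 107 km sandy gap with no
habitat, and a northern block that is itself split by a site-free sandy
stretch holding the 50 km spat-collection beach, with two populations
north of it. Placing the convergence at the centre of the long gap (it is
configurable) makes both blocks drain toward the gap and export offshore
there; this is the package's way of realising the "two blocks with limited
exchange" structure robustly at desk scale — in the real system the
convergence lies inside the southern block and the separation is attributed
to the habitat gap plus the northward inshore flow. Sites north of the
beach sit upstream of it, so backtracked beach spat yield primary
settlement areas over the site-free stretch, forward-tracked larvae from
the upstream sites can reach those areas within their competency window,
and bottom-drifting spat from the areas reach the sites further south:
the full two-stage chain closes.

What the synthetic scenario does **not** emulate: tides, wind events,
river plumes, inter-annual circulation change (replicate "years" differ
only through seeded release positions, depths and turbulence draws),
vertical shear beyond the linear attenuation, and any realistic coastline
geometry. Passing tests therefore demonstrate that the machinery —
integration, bookkeeping, metrics, algebra — behaves correctly under
controlled conditions, not that the real region behaves this way.

## Problem sizes and numerical choices

Test-suite and acceptance-script runs are scaled down from the published
experiment sizes as this package's desk-scale defaults: experiment 3 runs
~2 × 10⁴ particles (49 sites × 20 points × 20 per point, one release
month, one replicate year); experiments 1, 2 and 4 run 500–2000 particles;
the diffusion calibration uses 10⁵ single-axis ensembles; Mantel
calibration uses 200 replicates of 999 permutations. The spat-age lag,
time step, diffusivities, sinking rate, competency windows, density
threshold and buffer keep their full-scale values throughout.

Numerical details worth knowing:

* Release instants are snapped to the integration step grid (at 900 s this
  is far below any other time scale in the model).
* Cell-level (not interpolated) bathymetry and land masks drive the
  boundary rule; velocities stored on land cells hold the smooth analytic
  continuation so that interpolation near the coast stays well defined,
  and the mask alone decides what is land.
* The RK4 radial error on circular motion is superconvergent (5th order);
  4th-order convergence is measured on the full endpoint error.
* Settlement-area polygons buffered by shapely approximate circular
  corners with 8 segments per quadrant (~0.2% area deficit on a single
  cell).
* A density grid with no samples in the age window is returned flagged
  empty rather than raising.
* The move-back boundary rule is not reversible; reversibility holds for
  trajectories that never touch the coast, and is tested on such.
* F_ST inputs are symmetrised checks, small negative estimates are clamped
  to zero with a warning; the comparison restricts both matrices to their
  shared populations and requires at least three.

## Known limitations

* No larval growth, mortality, temperature dependence or active swimming;
  the only behaviour is constant sinking.
* Spawning biomass is unweighted: every release point emits equally.
* Secondary-stage chaining through matrix products assumes the stage
  matrices are independent, as in the published two-stage construction.
* Straight-line kernel distances understate along-coast separation for
  convoluted coastlines (irrelevant for the straight synthetic coast).
* The counter-based RNG guarantees partition independence only while
  particle ids and the master seed are stable across runs.
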