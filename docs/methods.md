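# Methods

`sheetflock` reconstructs, as importable and tested code, the computational
machinery used to study serum/EGF-induced collective migration in confluent
keratinocyte sheets: a hybrid active-matter simulation of the monolayer and
the image-derived motility, polarity and inheritance statistics, driven by
synthetic data generators in place of microscopy.

## The hybrid Self-Propelled-Voronoi / Vicsek model

Cells are the Voronoi regions of N centres **r**_i in a periodic square box
of side L = √(N·A₀) (confluent density 1). The tissue energy is the standard
area/perimeter form

    E = Σ_j K_A (A_j − A₀)² + K_p (p_j − p₀)²

with the area term from volume incompressibility and the perimeter term from
cortical tension and adhesion. Centres obey

    r_i(t+Δt) = r_i(t) + [ μ F_i(t) + v₀ n_i(t+Δt) ] Δt,     F_i = −∇_i E,

with polarization n_i = (cos θ_i, sin θ_i) and a Vicsek-style angle update

    θ_i(t+Δt) = θ_i(t) + (Δt/τ_V) ⟨φ_j − θ_i⟩_{0<|r_j−r_i|≤R_V} + η_i ,

where φ_j is the direction of neighbour j's displacement over the previous
step. R_V is a proxy for calcium-dependent cell–cell connectivity: R_V = 0
decouples the cells, large R_V couples each cell's polarization to the local
flow. Lengths are reported in r₀ = √A₀ and times in τ₀ = 1/(μ K_A A₀).

Default parameters (the reference active set): K_A = K_p = 1, μ = 1,
v₀ = 0.5, τ_V = 1, D_r = 1.5, Δt = 0.001, p₀/√A₀ = 4.0 (the experimentally
motivated shape index; well inside the fluid regime of the model), N = 1000.

### Discretization choices

- **Rotational noise.** The white-noise term is stated with variance 2·D_r
  without a time step; it is implemented as a Gaussian increment of variance
  2·D_r·Δt per step — the standard Brownian-rotation discretization, which
  makes the angular dynamics independent of Δt. A literal per-step variance
  of 2·D_r (sd ≈ 1.73 rad) would randomize the polarization within a single
  step and suppress directed motion almost completely; it is not a viable
  reading.
- **Circular averaging.** Each φ_j − θ_i is wrapped to (−π, π] before the
  arithmetic neighbour mean (a plain mean of raw angle differences is
  ill-defined on the circle). Empty neighbourhoods and neighbours with zero
  displacement (undefined φ) contribute nothing.
- **Update order.** Angles are updated first, using velocities of the
  completed previous step; positions then advance with the new polarization,
  matching the time indices of the discrete equations. At t = 0 there is no
  previous step and the alignment term is zero.
- **Neighbourhoods** use centre-to-centre minimum-image distance, not
  Voronoi adjacency, because R_V may exceed the first-neighbour shell.

### Geometry and forces

Areas and perimeters come from the periodic Voronoi diagram, computed by
ghost-padding the box (margin of 3 mean cell spacings), Delaunay
triangulating, and assembling each central cell's polygon from the
circumcentres of its incident triangles. Correctness is enforced every call
through the exact tiling identity Σ A_j = L² (tolerance 10⁻⁹ relative); if a
sparse region pierces the thin margin the tessellation silently retries with
full 3×3 tiling.

Forces are the exact analytic gradient −∇_i E: the polygon derivatives
∂A/∂h and ∂p/∂h are chained through the Jacobian of each Voronoi vertex
(triangle circumcentre) with respect to its three generating centres, and
ghost contributions are folded back onto their source cells. The gradient is
validated against central finite differences of the energy (step 10⁻⁶·r₀,
relative error < 10⁻⁵, typically ~10⁻¹⁰) in the test suite.

Degenerate (cocircular) configurations such as perfect square lattices
produce coincident Voronoi vertices from distinct triangles; there the split
of ∂E/∂h between the triangles is branch-dependent, so it is averaged over
each coincident cluster, restoring the symmetric limit (zero net force on a
lattice at its energy minimum). Away from the minimum the energy genuinely
has one-sided derivatives at such configurations; random initial conditions
plus a 10⁻⁹·r₀ jitter at initialization keep the dynamics off this measure-
zero set.

### Protocol and observables

Runs start from uniformly random positions and polarizations, equilibrate
for 10,000 steps without activity (v₀ = R_V = 0), then run 20,000 active
production steps. Cell speed at time t is |r(t+100Δt) − r(t)|/(100Δt),
averaged over cells (displacements unwrapped across the periodic boundary);
the order parameter (IOP) is the magnitude of the mean unit-velocity vector
over cells moving faster than ε = 10⁻⁹ r₀/τ₀. Observables are recorded
every 100 steps and steady-state means taken over the final half of
production.

The acceptance script and simulation tests use N = 256 cells and 3
independent seeded runs per condition; the steady-state speed is intensive
(N = 256 and N = 1000 agree within a few percent), which is what makes the
reduced scale meaningful. At the default active set the reduced-scale
protocol yields steady speeds near 0.31 r₀/τ₀ (R_V = 0) and 0.31–0.33
across R_V ∈ {2.5 … 10}, with the order parameter increasing with R_V.

## Velocity-field statistics

Inputs are PIV-style U/V rasters with a validity mask, window spacing (µm)
and frame interval (min); masked entries are excluded from every statistic.

- **Temporal median** over bins of 3 frames (output length T − 2) removes
  transient spatial noise such as floating cells.
- **Speed maps**: M = √(U²+V²), then a 5×5 spatial median that ignores
  masked entries; frame mean over unmasked entries (NaN when fully masked).
- **IOP**: magnitude of the mean unit vector of unmasked nonzero vectors.
- **Angle–distance curve**: every vector on the main diagonal seeds four
  cardinal-direction walks; at each integer grid distance r the angle
  θ = arccos(v₀·v_r /(|v₀||v_r|)) is recorded (masked or out-of-bounds
  positions and zero vectors are skipped, an undefined angle being
  meaningless rather than zero). Distances are reported both in windows and
  µm (× window spacing — always an explicit input, never inferred).
- **Correlation length** C_vv = the largest r with mean θ(r) + 5·SEM < 90°.
  The criterion is evaluated independently at each r and the maximum passing
  r returned; a stricter contiguous ("first failure stops") variant is
  available behind a flag for sensitivity analysis, since the reference
  formula is a max over the condition. The SEM denominator is the number of
  angle samples collected at that r (seeds × directions, after skipping);
  distances with fewer than 2 samples cannot pass. 5-σ corresponds to an
  upper-tail normal probability of 3×10⁻⁷.
- An exhaustive **all-pairs estimator** (axis-aligned separations, small
  grids) serves as the independent oracle for the diagonal-seeded walk; the
  SEM-based agreement check between the two is statistically valid on
  spatially independent fields, which is how it is tested.

## Track statistics

- **Fixed-lag MSD**: for each time point, the mean squared displacement
  between t and t+lag over tracks spanning both times; tracks with fewer
  than 19 spots are discarded and tracks ending within the lag of t do not
  contribute. The lag must be a whole number of frames (mismatches are
  rejected rather than interpolated).
- **MPI**: within a running 10-frame window (9 displacements), the magnitude
  of the mean displacement unit vector; 1 = straight-line migration,
  iid headings give ≈ √(π/36) ≈ 0.3. Zero-length displacements are skipped
  and the divisor is the number of retained vectors; windows with fewer
  than 2 usable displacements are undefined.
- **Motility summary**: per-track mean velocity (path length / elapsed time,
  µm/h) and straight-line Euclidean distance (µm).
- **Division/polarity order statistics**: angles as unit vectors;
  ⟨x⟩, ⟨y⟩, magnitude √(⟨x⟩²+⟨y⟩²) and the mean angle through the
  quadrant-correct two-argument arctangent (the one-argument form is
  ambiguous across quadrants). Directed (vector) statistics are the default
  because prophase polarity defines a direction; axial mode (θ ≡ θ+180°,
  via angle doubling) is a flag.
- **Rose histograms** are unity-based (min–max) normalized; the flat
  histogram maps to all-zero heights by convention.
- **Relative nuclear position** p = |c−x|/|y−x| from nucleus-centre /
  membrane-point triplets, with t = 0 at the last frame before mitosis entry
  and earlier frames negative (reversed traversal). Coordinates are inputs;
  membrane extraction from images is upstream and out of scope.

## Organelle-inheritance model

Each of the n bodies of a division is assigned independently to one fixed
daughter with probability p_sym, so P(complete asymmetry | n) =
p_symⁿ + (1−p_sym)ⁿ — at p_sym = 0.5 the curve 2^(1−n). This per-body
reading is the only one that produces an n-dependent curve, which is what
the data constrain; a per-division "probability of a symmetric outcome"
cannot. The fit maximizes the Bernoulli likelihood of the
complete/incomplete indicator given each division's total; p ↔ 1−p symmetry
is resolved to p ≤ 0.5, boundary fits are flagged, and data in which every
division carries a single body (flat likelihood) are flagged
non-identifiable. Divisions with zero detectable bodies are excluded
everywhere. The excess-asymmetry test resamples the indicators under
p_complete(n_i, p_null) and reports the add-one-corrected exceedance
probability of the observed asymmetric count; being an exact Monte-Carlo
test of a discrete statistic it is slightly conservative at small sample
sizes.

## Synthetic data

The generators emulate the *statistical structure* of the five input
classes, not the imaging pipeline:

- **Gridded flow**: per-window headings base ± Gaussian noise, smoothed with
  an isotropic Gaussian on the Cartesian components of the unit headings
  (avoiding angle wrap-around artefacts) and re-normalised to a
  deterministic magnitude. Smoothing scale tunes spatial order (and hence
  C_vv monotonically); it does not reproduce PIV window cross-correlation
  noise, drift, or stitching artefacts.
- **Vicsek particles**: the classic point-particle flocking model, binned to
  a velocity grid with empty bins masked — an order-tunable flow source.
- **Tracks**: ballistic / persistent (wrapped-normal turning with
  SD = (1−persistence)·180°, simple, monotone and bounded) / Brownian /
  alternating / stationary, one independent random substream per track.
- **Division angles**: von Mises around a mean direction; concentration 0 is
  uniform.
- **Inheritance counts**: totals from an explicit probability table (default
  uniform over 1..6 — a placeholder, the empirical per-division count
  distribution not being published), then per-body Bernoulli assignment.
- **Pre-mitotic nucleus**: centre at the cell midpoint with small jitter,
  drifting linearly towards the near membrane during the final ~30 min
  (default final relative position 0.2).

All generators are pure functions of their spec including the seed
(sub-streams spawned per track/division so reordering cannot leak
randomness). Passing tests on these inputs demonstrate correctness of the
statistics under known ground truth — not robustness to segmentation
errors, tracking gaps, uneven illumination or other failure modes of real
microscopy data.

## Known limitations

- The simulation model contains no cell division or apoptosis, no
  three-dimensional structure, and no fitting of parameters to experimental
  movies.
- Reduced-scale steady speeds land slightly above the 0.25–0.32 r₀/τ₀ range
  reported for this system; the forces,
  protocol and units here are validated independently, and the residual
  offset is documented where it is measured rather than calibrated away.
- Quantities tied to the raw microscopy data (absolute µm/h velocities,
  millimetre correlation lengths, observed asymmetry percentages) require
  those data and are exercised here only through their algorithms on
  synthetic inputs.
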