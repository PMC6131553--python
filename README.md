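# sheetflock

Active-matter simulation and motility statistics for confluent epithelial
sheets.

Quiescent keratinocyte monolayers, re-stimulated with serum or EGF, launch
a burst of long-range collective migration without any wound edge: cells
self-propel, align with their neighbours' flow, divide along the migration
direction after the nucleus migrates to the cell front, and partition
organelles (PML-body assemblies, lysosomes) asymmetrically between
daughters. `sheetflock` packages the computational side of studying this
system — for modellers and image analysts who have velocity fields, track
tables, angle sets or daughter-cell counts (or want realistic synthetic
versions of them) and need the standard statistics computed reproducibly.

## What is inside

**Hybrid Self-Propelled-Voronoi / Vicsek simulator** (`sheetflock.sim`,
`sheetflock.voronoi`). Cells are Voronoi regions of N centres in a periodic
box with tissue energy

    E = Σ_j K_A (A_j − A₀)² + K_p (p_j − p₀)²

and dynamics

    r_i(t+Δt) = r_i(t) + [μ F_i(t) + v₀ n_i(t+Δt)] Δt,   F_i = −∇_i E
    θ_i(t+Δt) = θ_i(t) + (Δt/τ_V) ⟨φ_j − θ_i⟩_{0<|r_j−r_i|≤R_V} + η_i

— self-propulsion of speed v₀ along the polarization n_i = (cos θ_i,
sin θ_i), Vicsek alignment to the velocity directions φ_j of neighbours
within radius R_V (a proxy for calcium-dependent cell–cell connectivity),
rotational noise of strength D_r. Forces are the exact analytic gradient of
E through the Voronoi geometry, validated against finite differences.
Observables: mean cell speed (in r₀/τ₀ units) and the instantaneous order
parameter (IOP).

**Velocity-field statistics** (`sheetflock.flow`). Temporal/spatial median
filters, speed maps, per-frame IOP, the diagonal-seeded angle–distance
correlation curve and the 5-σ correlation length

    C_vv(t) = max r : ⟨θ⟩(r) + 5·SEM(θ(r)) < 90°,

plus an exhaustive all-pairs oracle for testing.

**Track statistics** (`sheetflock.tracks`). Fixed-lag (5 h) MSD with track
filtering, the migration persistency index (MPI: resultant length of
displacement unit vectors in a running 10-frame window), per-track motility
summaries, division-direction order statistics (⟨x⟩, ⟨y⟩, ‖⟨d⟩‖, ⟨θ⟩),
unity-normalized rose histograms and the relative nuclear position
p = |c−x|/|y−x|.

**Organelle-inheritance model** (`sheetflock.inheritance`). Binomial
partitioning: each of n bodies goes to one daughter with probability
p_sym, so P(complete asymmetry | n) = p_symⁿ + (1−p_sym)ⁿ; maximum-
likelihood fit of p_sym, observed asymmetry fractions and a Monte-Carlo
excess-asymmetry test.

**Synthetic data** (`sheetflock.synth`). Seeded generators for all five
input classes with tunable spatial order, persistence, angular
concentration and partition bias; `sheetflock.io` reads and writes the
portable formats (npz + JSON sidecar for field stacks, CSV for the rest).

## A worked example

```bash
python examples/inheritance_fit.py
```

```
complete-asymmetric fraction: 0.542 ± 0.025
ML partition parameter:       p_sym = 0.194 (true 0.2)
model curve P(complete | n):
  n = 1: fitted 1.000   symmetric null 1.000
  n = 2: fitted 0.687   symmetric null 0.500
  n = 3: fitted 0.531   symmetric null 0.250
  n = 4: fitted 0.423   symmetric null 0.125
  n = 5: fitted 0.340   symmetric null 0.062
  n = 6: fitted 0.274   symmetric null 0.031
excess over the symmetric null: exceedance probability = 9.999e-05
```

400 synthetic divisions were generated with a biased partition (p_sym =
0.2): 54% of them put every body into a single daughter. The fit recovers
p_sym ≈ 0.19, and the fitted complete-asymmetry curve sits far above the
symmetric-null curve 2^(1−n); the Monte-Carlo exceedance probability
(~10⁻⁴, the resolution floor of 10⁴ resamples) says such an excess cannot
arise from unbiased partitioning.

The other examples follow the same pattern, one per capability:
`simulate_sheet.py` (steady speed ≈ 0.3 r₀/τ₀ and rising order for a
64-cell active sheet), `correlation_length.py` (C_vv = 4230 µm for a
smoothed field vs 0 for independent angles), `track_statistics.py`
(persistent vs Brownian MSD and MPI) and `division_polarity.py`
(order magnitude 0.85 for concentrated vs 0.01 for uniform division
angles; nuclear position leaving the cell midpoint ~30 min before
mitosis).

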