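# Methods

## Model

The simulation is a two-dimensional Cellular Potts Model on a rectangular
site grid `labels[z, x]` (0-based, `z = 0` at the bottom).  Every site
carries exactly one label: a positive cell id, MEDIUM (0), SUBSTRATE (−1)
or WALL (−2).  A one-site wall ring frames the lattice so cells never touch
the array edge; a frozen substrate strip (width 450 px at production scale,
3 px thick, configurable) rests on the bottom wall; simulations start from
one square cell of side `round(√A0)` centered on the substrate.  Wall and
substrate are frozen: they are never the source or target of a copy
attempt, and attempts that pick them (or pick two equal labels) still count
toward the step's attempt budget.

The energy has three terms per the model summary in the README: quadratic
area compressibility about the target area `A0`, quadratic cortical
contractility on the boundary-link count (a cortex spring with zero rest
length), and contact energies on unlike neighbor pairs.  Conventions that
any reimplementation must fix explicitly:

- **Contact (J) sum** — each *unordered* neighbor pair is counted once,
  over the order-2 (8-site) neighborhood by default.  `J` is
  `λ_adh^cc` for cell–cell pairs, `λ_adh^cs` for cell–substrate pairs, and
  0 whenever either site is medium or wall.
- **Perimeter `L_σ`** — order-1 face links between a cell pixel and a pixel
  of any other label, so a `w × h` rectangle has `L = 2(w + h)` exactly,
  matching the analytic rectangle below.  Only in-lattice links exist.
- **`n_s`** — the number of a cell's *pixels* with at least one
  face-adjacent substrate pixel (adhesion sites), not a link count.
- Medium carries no area or perimeter terms; cell fragmentation is
  permitted (no connectivity constraint), as in the plain Potts model.

Both neighborhood orders are configuration knobs (orders 1–4 supported).
The contact order matters quantitatively: it scales the effective lateral
cell–cell adhesion per unit interface length and thereby shifts phase
boundaries and the steady monolayer cell height (see Limitations).

## Dynamics

An elementary step picks a uniform random site and a uniform random face
neighbor, computes the incremental `ΔE` (touching only the affected cells'
terms and the links incident to the target site; verified against full
recomputation to 1e−9 relative), and accepts with the Metropolis rule at
temperature `T`.  One MCS = `width × height` attempts.  The production
loop runs a numba-compiled kernel with an inline xorshift64* generator; the
kernel consumes one 31-bit seed per MCS drawn from the run's
`numpy.random.Generator`, so a trajectory is a pure function of
`(parameters, seed)` and identical seeds give bit-identical snapshot
sequences.

After each MCS (unless division is disabled) cells are visited in
randomized order; each with `A_σ ≥ A0` (cached area at sweep time) divides
with the Hill probability of its `n_s`, at most once per sweep.  Mitosis
partitions the mother's pixels by signed distance to the plane through its
centroid; pixels exactly on the plane go as a block to the side currently
holding fewer pixels (keeping daughters as close to `A0/2` as the geometry
allows), and the fresh id takes the side with larger mean `x` (mean `z` as
tiebreak) — deterministic rules chosen for reproducibility.  A split that
would leave one side empty is aborted without state change.  Major-axis
orientation uses the principal eigenvector of the pixel-position
covariance; isotropic second moments (e.g. a square) fall back to a
uniform random plane angle.

**Steady state** is operational: no division event within a sliding window
(default 500 MCS) *and* the mean total energy of the window's two halves
agreeing to a relative tolerance (default 1e−3).  A drift test is used
rather than a range test because the `T`-driven fluctuation floor never
shrinks.  Both knobs are parameters.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `lambda_area` | area compressibility | energy/px⁴ | 1 |
| `lambda_cont` | cortical contractility | energy/link² | 3 |
| `lambda_adh_cc` | cell–cell contact energy | energy/link | −150 |
| `lambda_adh_cs` | cell–substrate contact energy | energy/link | −300 |
| `A0` | target cell area | px² | 225 |
| `T` | Potts temperature | energy | 50 |
| `gamma`, `k`, `P_max` | Hill division law | — | 2, 10, 0.1 |
| lattice | width × height | px | 480 × 195 |
| substrate | width × thickness | px | 450 × 3 |

The Hill half-saturation count is `γ√A0` (= 30 at defaults), i.e. twice
the footprint of a square resting cell.  The four λ defaults are the
center of the collective phase-diagram axes explored in the experiments
module (`λ_cont ∈ [1,7]`, `λ_adh^cs ∈ [−700,−100]`, `λ_area ∈ {1,70}`,
adhesion ratio `α = λ_adh^cs/λ_adh^cc ∈ {2,20}`).  The substrate thickness
(3 px) is the smallest value that hides the bottom wall from cells under
any supported contact neighborhood.

`reduced_preset()` is the desk-scale configuration used by the test suite
and the acceptance script: 240 × 100 lattice, 220 px substrate, 10,000-MCS
budget, snapshots every 50 MCS.  Shape metrics are local, so the narrower
domain reproduces the same cell morphologies as production scale at a
fraction of the cost; it holds roughly half as many cells, which widens
seed-to-seed variability of collective observables.

## Analytic rectangle

For an isolated rectangular cell of length `l` and height `h`,
`E(l,h) = λ_area(lh−A0)² + λ_cont(2l+2h)² + λ_adh^cs·l` (the substrate
boundary has length `l`; all other boundaries face medium at `J = 0`).
`rect_equilibrium` minimizes over the box `(0, 4√A0]²` by multi-start
L-BFGS-B seeded from a coarse grid, with the analytic gradient; results are
certified in tests against an exhaustive 0.01-px grid.  In shallow valleys
(small `λ_area`) the grid argmin wanders along near-degenerate directions,
so certification accepts either coordinate agreement within one grid step
or a continuous minimum at least as deep as every grid point.  Minimizers
within 1e−6 of the box edge are flagged `on_boundary` (strong-adhesion
parameter corners push `l*` to the box).

## Morphometrics and classification

Per-cell height and width are bounding extents (`z_max − z_min + 1`),
robust on pixelated shapes.  A cell is basal iff `n_s > 0`.  Coverage is
the fraction of top-substrate pixels with a cell directly above.  The
structure classifier labels a finished trajectory: `non_confluent`
(divisions ceased below the coverage threshold), `monolayer_squamous /
_cuboidal / _columnar` (confluent, no persistent suprabasal population,
divisions ceased; aspect bands at `1 ± 0.25`), `multilayer` (persistent or
growing suprabasal population), `multilayer_slow` (additionally, cell-count
growth below 20 % of a supplied reference rate, e.g. a sweep's fastest
corner).  The confluence threshold is 0.95 rather than exactly 1 because at
`T = 50` a fully formed layer transiently exposes single substrate pixels.
All thresholds live in `ClassifyThresholds`.

`mean_steady_cell_height` averages interior basal-cell heights over the
trailing steady window, excluding one cell at each end of the layer:
border cells abut bare substrate and are systematically wider and flatter
than layer-interior cells.

## Adhesion-ratio height experiment

`adhesion_ratio_height_experiment` (used by `scripts/acceptance.py`)
compares steady monolayer heights between `α = 2` and `α = 20` at fixed
`λ_adh^cs`, vertical division, `λ_area = 1`, five seeds per arm on the
reduced preset.  Runs use the full fixed 10,000-MCS budget rather than the
early-arrest stop so both arms are measured at the same simulated time.
Strong lateral adhesion (`α = 2`) stabilizes tall lateral interfaces and
sustains slightly larger steady areas, giving a height ratio above 1.

## What the desk-scale runs do and do not show

The desk-scale experiments reproduce the qualitative structure of the
collective phase diagram — non-confluent arrest at high contractility and
weak substrate adhesion, self-arresting confluent monolayers at strong
substrate adhesion under vertical division, continuously stratifying
multilayers at stiff area constraint and low contractility — and the
division-orientation mechanism (major-axis division of columnar cells
extrudes daughters; vertical division does not).

They understate the *magnitude* of the adhesion-ratio height effect.  A
large height ratio requires the strong-adhesion arm to keep dividing after
confluence, packing more, narrower, taller cells.  Post-confluence division
is gated by `A_σ ≥ A0`; with `λ_area = 1` and order-2 contact energies the
crowded-layer equilibrium area sits just below `A0`, and the collective
layer-thickening mode relaxes over far more than 10⁴ MCS, so both arms
arrest at nearly equal cell numbers and the measured ratio at
`λ_cont = 3, λ_adh^cs = −300` is ≈ 1.2 rather than the ≈ 1.9 expected at
full scale and full equilibration.  The squamous-corner ratio
(`λ_cont = 7, λ_adh^cs = −700`, ≈ 1.1) is much closer to its full-scale
value because those layers equilibrate faster.  Raising the contact order
strengthens the divergence mechanism but adds seed variance at this cell
count without closing the gap; the order-2 default was kept.

## Known limitations

- No cell death or differentiation; multilayers stratify indefinitely
  (within the lattice) instead of reaching homeostasis.
- No cytoskeletal term: at strong substrate adhesion and low contractility,
  unrealistically thin flattened shapes appear.
- 2D cross-section only; no periodic boundaries; a single cell type.
- Serial dynamics by design — fidelity to the elementary-step process over
  parallel updating.
- Extruded cells that re-adhere are simply counted basal again; there is no
  lineage-aware re-identification.
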