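# Methods

## Model

The simulator couples three layers on an `L × L` square lattice with unit
grid spacing and the cell cycle `τ` as the time unit (all rates are per grid
and per cycle):

1. **Nutrient reaction–diffusion.** A single generalized "nutrient"
   `φ ∈ [0, 1]` stands in for oxygen, glucose and the other species a cell
   cycle consumes. It evolves as

       ∂φ/∂t = D ∇²φ − k N_T φ,

   with `N_T` the per-grid living-cell count, integrated by an explicit
   5-point stencil in `n_sub` equal substeps per cycle (stability requires
   `D/n_sub ≤ 1/4`). All four domain edges are Dirichlet boundaries held at
   `φ = 1`: the vasculature surrounding the tissue is a stable source. The
   field is clamped to `[0, 1]` after every substep. The sink proportional
   to `φ` keeps the field non-negative naturally; a concentration-independent
   sink `−k N_T` (with clamping) is selectable via `consumption_form`.
   Living counts are frozen during the substeps of one cycle; the field is
   *not* iterated to steady state — `n_sub` is a model knob (default 8).

2. **ECM degradation and placement eligibility.** The host tissue is a
   density field `ρ_ecm ∈ [0, 1]`, initialized i.i.d. uniform, that living
   cells degrade at rate `γ` per cell per cycle. A tumor cell can only be
   placed on a grid with `ρ_ecm` exactly 0. Because a continuous-uniform
   initial field has no zero-density grids, a strictly-local degradation
   footprint would trap the founder forever; by default a living cell
   therefore degrades its own grid *and* its 8 Moore neighbors at the same
   rate. This neighborhood footprint is the largest single modeling choice
   in the package; the strictly-local variant is kept behind
   `degrade_neighbors=false` and covered by a regression test documenting
   the trapped-founder behavior. Degradation arithmetic clamps at exactly
   0.0 so the strict-zero eligibility predicate is well defined in floating
   point.

3. **Phenotype dynamics.** Living cells are proliferative or invasive.
   Each cycle proceeds: ECM degradation → nutrient update → necrosis →
   fate draws → synchronous placement.

   *Necrosis.* Every living cell in a grid whose renewed nutrient satisfies
   `φ < φ_c` (strict) becomes necrotic. Necrosis is absorbing: necrotic
   cells never move, never interact, and are never removed. Reversible
   quiescence is deliberately not modeled as a distinct state.

   *Fates.* For a cell in a grid with nutrient `φ` and living count `N_T`,

       P_p = clamp(1 − exp(−(φ/(N_T θ_p))²) + Δ_p, 0, 1)
       P_i = clamp(    exp(−(φ/(N_T θ_i))²) + Δ_i, 0, 1),

   then the pair is normalized to sum to 1 and the fate is sampled; if both
   raw values are 0 the cell holds (no action) for the cycle, since the
   normalization is undefined at 0/0. The saturating Gaussian-in-`1/x`
   forms encode that division becomes likely once the nutrient share per
   cell `φ/N_T` is large, and migration takes over when it is small. They
   are ordinary functions (`proliferation_probability`,
   `invasion_probability`) so alternative response curves can be swapped
   without touching the scheduler. `Δ_p, Δ_i` are the game increments: with
   `n_P` proliferative and `n_I` invasive living neighbors (same grid
   excluding the focal cell, plus the 8 Moore grids, phenotypes frozen at
   the previous round),

       Δ_p = agg(a_pp n_P + a_pi n_I),   Δ_i = agg(b_ip n_P + b_ii n_I),

   where `agg` divides by `n_P + n_I` by default (mean over interaction
   partners, keeping increments bounded as density grows) or is the
   identity (`payoff_aggregation="sum"`). Both increments are applied to
   every living cell regardless of its own label. The conventional signed
   construction stores the proliferative–proliferative entry as an
   inhibition (`a_pp = −α_pp ≤ 0`) and the invasive–invasive entry as an
   enhancement (`b_ii = +β_ii ≥ 0`); the cross terms default to 0.

   *Placement.* All divisions and migrations are applied synchronously: the
   counts (necrotic included) and the nutrient field used by every
   placement comparison are frozen at the start of the placement phase, so
   update order carries no bias, and multiple arrivals at one grid in the
   same cycle are allowed. A daughter's candidate set is the current grid
   plus the ECM-free Moore neighbors; a migrant's is the ECM-free Moore
   neighbors only (it stays if all are blocked). Selection is
   lexicographic: minimum total cell count, then maximum nutrient, then
   uniform random among ties. A dividing parent keeps its grid and carries
   the proliferative label for the round; a migrating cell carries the
   invasive label.

The run starts from one proliferative founder in the central grid (whose
ECM is cleared at initialization so the occupancy invariant holds from
`t = 0`) and stops when any tumor cell reaches the boundary ring or after
`t_max` cycles.

## Randomness and reproducibility

One `numpy` Generator per simulation, seeded from the configuration.
Draws are consumed in a fixed, documented order: initial fields (ECM, then
nutrient); then per cycle, proliferative-class fate draws over occupied
grids in row-major order, invasive-class draws, then placement tie-breaks
grid by grid in row-major order. Fate draws are batched binomials and tie
allocations batched multinomials — distribution-identical to per-cell
draws, which the test suite verifies against a literal per-agent reference
implementation on a 9 × 9 lattice (2000 replicates per implementation,
two-sample KS tests at α = 0.01). Two runs with equal configurations are
bit-identical; sweep trials derive independent sub-seeds from the base seed
and the grid-point/trial indices through a seed sequence.

## Morphometrics

* **Front profile:** polar origin at the founding grid; 360 angular bins by
  default; per bin, the *maximum* Euclidean radius over living-cell grids.
  Empty bins are flagged and excluded, never interpolated.
* **Mean front radius `r(t)`** is the unweighted mean over occupied bins;
  its OLS slope after a burn-in (default 30 τ) is the growth velocity `v`.
* **Surface roughness `R(t)`** is the population (1/N) standard deviation
  of the occupied bins' radii — the interface width of the growth front;
  its OLS slope is the roughness velocity `v_r`. Bins are unweighted;
  arc-length weighting was considered and rejected as a default because the
  unweighted convention matches the per-bin front definition.
* **Radial distribution function:** the domain is split into four angular
  quadrants; within a quadrant, `g(r) = n(r)/(N_s Δr)` with `n(r)` the
  living-cell count at radius `[r, r + Δr)` and `N_s` the quadrant's living
  total, so each RDF integrates to exactly 1 (a probability density of
  radial position; an annulus-area-normalized variant would describe
  density per unit area instead and is intentionally not the default).

## Default parameters and calibration

| parameter | default | meaning |
|---|---|---|
| `L` | 401 | lattice side (odd, so a central grid exists) |
| `t_max` | 200 τ | run length |
| `D` | 1.0 grid²/τ | nutrient diffusivity |
| `k` | 0.2 /τ | consumption per living cell |
| `phi_c` | 0.06 | necrosis threshold |
| `theta_p`, `theta_i` | 0.018 | fate-response shape parameters |
| `gamma` | 0.4 /cell/τ | ECM degradation rate |
| `alpha_pp`, `beta_ii` | 0.1 | reference payoff magnitudes |
| `n_sub` | 8 | diffusion substeps per τ |

The rate constants are not measured quantities; they were calibrated, once,
so that the default study reproduces the canonical avascular-spheroid
phenomenology on the half-size `calibration` lattice (201 × 201, chosen so
a quantitative run takes seconds rather than minutes): the necrotic
fraction plateaus at 0.90 ± 0.01 across seeds; the invasive fraction peaks
near cycle 12 and ends at ≈ 0.07; necrotic cells first appear at cycle
10–11; the median living-cell count over occupied grids is 4; the front
radius grows linearly (R² > 0.999) at ≈ 1.13 grids/τ; and `R(t)` grows as
`t^β` with `β = 0.94–1.00`. These six constraints pin the parameter set
tightly — in particular `θ` must be small (≈ 0.02) so that front cells
divide reliably while crowded interior cells switch to migration, and
`k` large enough (0.2) that the nutrient crash behind the front arrives by
cycle ~10. The plateau depends on domain size through the halt radius (the
living rim is an `O(1/r)` fraction of the mass): the full 401-lattice run
plateaus near 0.95.

## Numerical choices

* Strict inequalities at thresholds: necrosis at `φ < φ_c`; eligibility at
  `ρ_ecm == 0` exactly (degradation clamps to exact zero).
* Explicit-scheme stability `D·dt ≤ 1/4` is enforced at configuration
  validation and again in `NutrientParams`.
* `validate_config` accepts `t_max = 0` (a degenerate run returning the
  initial state and one record).
* Metrics raise `MetricError` on degenerate inputs (no living cells, fewer
  than two occupied bins, empty sectors) rather than returning sentinels;
  the per-cycle recorder stores NaN where a statistic is undefined (e.g.
  roughness at `t = 0`).
* The vectorized diffusion kernel is tested against a brute-force
  double-loop stencil oracle on 100 random 15 × 15 instances at 1e-12.

## What the synthetic initial conditions do and do not capture

All inputs are generated internally: i.i.d. uniform ECM and nutrient
fields and a single founder cell. Real stroma is spatially correlated and
structured (fiber networks, vessels, cell-scale granularity), real spheroid
experiments start from thousands of cells, and real nutrient supply is not
a perfect constant-concentration boundary. Passing tests therefore
demonstrate internal consistency of the model and reproducibility of its
emergent statistics, not quantitative agreement with any particular
experiment. Heterogeneous ECM initializations (e.g. Voronoi-tessellated
stroma), direction-dependent diffusion, and 3D lattices are out of scope.

## Known limitations

Two pieces of reference phenomenology are *not* reproduced by this
reconstruction, and the corresponding tests in `tests/test_acceptance.py`
are expected to fail — they are kept failing deliberately as documentation
rather than weakened:

* **Dense necrotic packing.** Reported spheroid cross-sections combine a
  sparse living rim (median < 5 cells/grid) with a densely packed necrotic
  core (modal count ≥ 10). Here a grid's final necrotic count equals its
  living count at the moment the nutrient crash sweeps it, and post-mortem
  top-up (migrants dying inside already-necrotic grids) is negligible
  (~3% of grids), so median living occupancy and modal necrotic count are
  locked together; parameter scans over `θ ∈ [0.001, 0.6]`,
  `k ∈ [0.01, 0.3]`, `φ_c ∈ [0.03, 0.45]`, `γ ∈ [0.03, 0.4]`, `D ∈ [1, 2]`
  and both consumption forms found no regime with both features at once.
* **Roughness–payoff trend.** The reference trend has the roughness
  velocity `⟨v_r⟩` increasing with the inhibition `α_pp` and decreasing
  with the enhancement `β_ii`. At the calibrated defaults the measured
  effect is small and reversed for `α_pp` (25 trials per corner:
  `⟨v_r⟩(α_pp=0.9, β_ii=0.1) = 0.1112` vs
  `⟨v_r⟩(α_pp=0.1, β_ii=0.9) = 0.1118`): under the normalized two-fate
  rule, both payoffs act by converting front divisions into migrations,
  and migrants preferentially backfill the least-crowded lagging bins, so
  each payoff *smooths* the front. Slow-front (ECM-limited, small `γ`) and
  mixed-front (large `θ`, high `φ_c`) regimes were probed as well; payoff
  effects there are dominated by seed-to-seed noise with unstable sign.

Other limitations: no cell removal or lysis (total count is monotone); no
mutation or genotype layer; quiescence is not a tracked state; the per-bin
maximal-radius front makes the growth velocity saturate near 1.13 grids/τ
(the diagonal-corrected ballistic limit) whenever front cells divide almost
surely, which blunts the sensitivity of `v` to the payoff parameters.
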