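# Methods

## Models and assumptions

The chemostat model tracks two species densities and three nutrient
concentrations in a well-stirred vessel with equal in- and outflow at rate
Φ. Growth of species *i* is a product of two Monod factors (strict
dependence on both the shared carbon source and the partner's metabolite),
death is negligible against dilution, and nutrient production/consumption
is proportional to growth with constants ν (positive for production,
negative for consumption). With no biomass the nutrients relax to their
inflow concentrations.

The reduced model follows from three steps: (i) eliminating the nutrients
through the dilution relations — the quantities Qⱼ = Sⱼ − Σᵢ νⱼᵢXᵢ obey
dQⱼ/dt = Φ(S̃ⱼ − Qⱼ) regardless of the dynamics, so after a few dilution
times Sⱼ ≈ S̃ⱼ + Σᵢ νⱼᵢXᵢ; (ii) expanding the Monod factors for K ≫ S;
(iii) dropping higher-order terms. The result is a Lotka-Volterra-like
system whose per-capita growth is quadratic in the partner density:
mutualism (b₁₂X₂) dominates at low density, competition (−c₁X₂²) at high
density. Only steady states are faithfully mapped; transients are not
(step (i) discards them by construction), and none of the package's
analyses rely on reduced-model transients.

### The growth-rate channel of the mapping

The plain reading of the mapping gives rᵢ = μᵢ/(Kᵢ₀·Kⱼᵢ), which yields
r = 0.04 for the reference chemostat set, whereas the reference reduced set
lists r = 0.027. The discrepancy is a constant factor (0.675) originating
in the Taylor base point of the derivation, which cannot be reconstructed
from the printed constants alone. `reduce_to_lv` therefore exposes the
plain mapping plus an `r_scale` override, with `r_scale="eq6"` selecting
the factor fixed by the printed pair (μ = 1600 ↔ r = 0.027). Analyses that
compare the two models across parameters (regime agreement, reduction
fidelity) use the printed-pair scale, since that is the correspondence the
reference reduced set itself embodies; with the plain scale the reference
chemostat set would sit exactly on the reduced model's transcritical
boundary (r·a − d = 0). Quantities that depend on the r-channel are
otherwise avoided as cross-model checks.

## Numerical choices

- **Integration**: adaptive LSODA with rtol 1e−8 / atol 1e−10 by default;
  `simulate` defaults to a horizon of 50 dilution times.
  `simulate_to_steady` starts at 100 dilution times and doubles (up to 3
  times) until the scaled vector-field norm falls below 1e−7; survey and
  basin protocols use this convergence-aware driver. Round-off negatives
  are clipped to zero before outcome classification.
- **Extinction threshold**: 1e−6 density units (configurable). Survival of
  species *i* means final density above this threshold.
- **Reduced-model fixed points**: E, L1, L2 in closed form; all interior
  intersections via substitution of the explicit parabola into the second
  nullcline, giving a degree-≤4 polynomial solved by companion-matrix
  eigenvalues, then 2-D Newton polish on the per-capita equations. This
  global route is what finds all four intersections in the
  weak-self-inhibition regime where a pure Newton search can miss pairs.
  Duplicates are merged at 1e−6 relative; positivity cut at 1e−9.
- **Chemostat fixed points**: at any steady state the dilution relations
  pin Sⱼ = S̃ⱼ + Σᵢ νⱼᵢXᵢ exactly, collapsing the problem to the two
  densities. The washout state is emitted analytically (residual exactly
  zero); boundary states are bracketed scalar roots on the feasible density
  interval; interior states come from multi-start Newton (density grid,
  reduced-model predictions, seeded log-uniform random starts with default
  seed 0, optionally endpoints of the ten-inoculum simulation protocol),
  each polished on the full five-variable system with the analytic 5×5
  Jacobian and kept only below residual tolerance (1e−9 relative to
  Φ·S̃₀).
- **Stability**: eigenvalues of the analytic Jacobians; stable means all
  real parts < −1e−9, with a marginal flag when any real part lies within
  ±1e−9 of zero. Strict inequalities in the condition reports use a 1e−12
  relative guard band.
- **Uniqueness conditions** (at most two coexistence states): implemented
  from the vertex geometry — each parabola's maximum height must lie beyond
  the other's vertex abscissa, b₂₁/(2c₂) > (a₁ − d/r₁ + b₁₂²/(4c₁))/b₁₁ and
  symmetrically; the inequality actually evaluated is recorded in the audit
  string. The conditions are sufficient, not necessary, and are tested in
  that direction against brute-force intersection counting. Two documented
  degenerate cases return trivially true: c = 0 (parabola degenerates to a
  line) and b₁₂, b₂₁ ≤ 0 (no mutualistic bending, both alive branches
  monotone on the positive quadrant).
- **Branch tracing**: the symmetric sweep (r₁ = r₂) re-enumerates fixed
  points per sweep value; a change in the number of coexistence states is
  refined by bisection and classified as a saddle-node (two interior roots
  merge) or transcritical (a root's coordinate passes through zero);
  transcriticals of the extinction state are detected independently from
  its leading eigenvalue r·a − d. Closed forms for the symmetric case,
  r_T = d/a and r_SN = d/(a + (b₁₂−b₁₁)²/(4c)), serve as oracles: the
  latter is the zero-discriminant point of the diagonal quadratic
  cX² − (b₁₂−b₁₁)X + (d/r − a) = 0.
- **Basins**: each grid cell is integrated to steadiness and matched to the
  nearest stable state within 1e−3 relative (absolute floor 1e−3 for the
  origin); unmatched cells carry a sentinel and are counted. Default grid:
  101×101 over 1.5× the largest attractor coordinate. Separatrix
  extraction by manifold integration is deliberately not implemented — the
  basin boundary itself carries the same information for these purposes.
- **Regime maps**: 41×41 default resolution; per-cell chemostat
  classification uses fixed-point enumeration with a fallback to the
  ten-inoculum simulation protocol when Newton finds no stable state;
  failures label the cell `other`, never abort a scan.

## The survey generator

Each draw is a full chemostat parameter set. Kinetic constants (Φ, μ, K,
and the ν magnitudes) are log-uniform over two decades centred on the
reference values, with the sign pattern of the cross-feeding scheme held
fixed (carbon consumed by both, each metabolite produced by one species and
consumed by the other). The two modes differ in the inflows:

- **unconstrained**: the three inflow concentrations are exchangeable —
  each is drawn log-uniformly from one shared range, 0.1 to 500 (the union
  of the per-nutrient centred spans). Centring each inflow on its reference
  value would quietly privilege the carbon source fifty-fold and thereby
  bake the "constrained" operating regime into the supposedly unconstrained
  draw.
- **constrained**: S̃₀ pinned at 50 with S̃₁, S̃₂ log-uniform on [0.1, 2] —
  the high-carbon / low-metabolite regime that strengthens the
  cross-feeding feedback loop.

Every range is overridable through `SamplingSpec`, so alternative protocols
can be expressed exactly. The bistability verdict simulates from ten fixed
initial-density pairs spreading over [0, 20]² (corners, diagonal and
flanks), integrates each to steadiness (survey tolerances rtol 1e−6 /
atol 1e−9, horizon 100 dilution times with doubling), clusters converged
endpoints at 1e−3 relative, and calls a draw bistable when at least two
distinct attractors are reached. Draws where no start converges are
indeterminate and never counted as bistable; the headline fraction uses the
full denominator (a determinate-only fraction is exposed separately), with
an exact Clopper-Pearson interval. An optional cross-check compares the
verdict against the ODE-free fixed-point enumeration; disagreements are
counted in the result, not silently resolved.

What the generator does *not* emulate: measurement noise, stochastic
demography at low density, lag phases or other non-Monod kinetics, and more
than two species. Passing tests therefore speak to the deterministic
two-species Monod chemostat, not to data from real cultures. The bistable
fraction is strongly range-sensitive: under these documented defaults the
constrained mode measures ≈4–6% while the unconstrained mode measures
≈0.2–0.3% — rare, but the precise value should be read as a property of
the declared sampling plan rather than of the model alone.

## Problem sizes used in the shipped checks

The test suite uses a 21×21 growth-rate grid for the cross-model regime
comparison, 100–200 random parameter sets for the oracle-equivalence and
property checks, 2000 draws per survey mode, and 121-point sweeps for
bifurcation tracing; the examples use smaller grids. All are the package's
own defaults for quick, reproducible analysis and can be raised freely.

## Known limitations

- The reduced model's transients are not meaningful; only steady-state
  structure is compared across models.
- The growth-rate channel of the reduction is fixed only up to the
  documented scale factor (see above).
- Regime boundaries from grid scans are resolved only to grid resolution;
  use `branch_trace_1d` or the closed forms for precise thresholds.
- No limit-cycle or chaotic-attractor detection: all analyses assume
  convergence to fixed points, which holds throughout the explored
  parameter ranges but is asserted, not proven, by the convergence checks.
- The survey's indeterminate draws (non-converged within the doubled
  horizon) are rare (≲0.5%) but counted conservatively.
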