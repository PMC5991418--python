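# mutucomp

Tools for analysing bistability in a pair of microbial species that
**compete** for a shared carbon source while being **mutualists** through
cross-feeding — a motif common in gut and soil communities, where two
strains share a substrate but each produces a metabolite (e.g. a
short-chain fatty acid) the other needs.

The package is aimed at theoretical ecologists and systems biologists who
want to go from a mechanistic chemostat description to an interpretable
phase-plane picture: it implements both models, the mapping between them,
and the full steady-state analysis toolkit (fixed points, stability,
nullclines, basins of attraction, regime maps, bifurcation tracing, and a
Monte-Carlo bistability survey).

## The models

**Chemostat** (five variables; densities X₁, X₂ and nutrient
concentrations S₀, S₁, S₂):

```
dXᵢ/dt = (fᵢ − Φ) Xᵢ
dSⱼ/dt = Φ (S̃ⱼ − Sⱼ) + Σᵢ νⱼᵢ fᵢ Xᵢ
```

with double-Monod growth, e.g. f₁(S₀, S₂) = μ₁ · S₀/(K₁₀+S₀) · S₂/(K₁₂+S₂):
each species strictly requires both the carbon source and its partner's
metabolite. Φ is the flow rate, S̃ⱼ the inflow concentrations, and the
νⱼᵢ are production (positive) / consumption (negative) constants.

**Extended Lotka-Volterra reduction** (two variables): eliminating the
nutrients through the dilution relations and linearising the Monod factors
yields

```
dX₁/dt = ( r₁ (a₁ − b₁₁X₁ + b₁₂X₂ − c₁X₂²) − d ) X₁     (and symmetrically)
```

where `d = Φ` is the outflow/death rate, `a` carries the nutrient inflows,
`b₁₁` self-inhibition, `b₁₂` mutualism and `c` the quadratic competition
term — mutualism dominates at low partner density, competition at high
density. Unlike the classical Lotka-Volterra equations, which carry a
single signed interaction coefficient per pair, this form represents both
interactions at once, and its nullclines are parabolae that can be read
directly in the phase plane.

Steady states are named `E` (both extinct), `L1`/`L2` (one survivor) and
`L12` (coexistence); parameter regimes `R1`–`R7` are named by which of
these are stable (e.g. `R4` = bistability between extinction and
coexistence).

## Worked example

```python
from mutucomp import elv_fixed_points, fixture, reduce_to_lv

chem = fixture("eq3")                       # reference chemostat set
lv = reduce_to_lv(chem)                     # leading-order reduction
print(lv.d, (lv.a1, lv.a2), (lv.b11, lv.b12, lv.b21, lv.b22), (lv.c1, lv.c2))
# 2.0 (50.0, 50.0) (5.0, 10.0, 10.0, 5.0) (0.2, 0.2)

for fp in elv_fixed_points(fixture("eq6")):
    print(fp.label, fp.coords.round(3), fp.verdict)
# E   [0. 0.]           stable
# L12 [6.51 6.51]       saddle
# L12 [18.49 18.49]     stable
```

The reduction maps the chemostat constants onto the reduced set (outflow
rate 2, inflow terms 50, mutualism 10 vs self-inhibition 5, competition
0.2). At these values the reduced model is bistable: extinction `E` and
coexistence `L12` at (18.49, 18.49) are both stable, separated by the
saddle at (6.51, 6.51) whose stable manifold forms the basin boundary.

The `examples/` directory contains one short script per capability
(simulation and outcome classification, reduction and bistability
conditions, fixed points and basins, regime maps and bifurcation tracing,
and the random-parameter survey); each prints the numbers it computes and a
line on what they mean. A thin CLI exposes the same operations:

```
mutucomp fixedpoints --fixture eq6
mutucomp reduce --fixture eq3 --out out/
mutucomp survey --n 1000 --constrained --out out/
```

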