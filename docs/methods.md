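# Methods

## Scope and intent

`oceanfarm` is a strategic (theoretical) model: it asks how the joint
FAD-and-MPA character of ocean farms plays out for a generic fished
stock, not what will happen at a particular site. Every quantity is in
model units; the value of a run lies in the *relative* outcomes δB and
δC against the no-farm baseline, which are insensitive to the absolute
biomass scale (the dynamics are homogeneous of degree one in carrying
capacity and abundance, which is also how the carrying-capacity
calibration works).

## Population model

The stock occupies a 1-D lattice of 100 equal patches with wrapped
edges, so no patch is special; all layout choices are
translation-equivariant (asserted in tests). The state is numbers- and
weight-at-age per patch with an annual step and a plus group at age 20.

**Movement.** Adults move through a row-stochastic Gaussian kernel over
wrapped distance with scale σ_m. A species' mobility is specified as the
fraction of the domain its home range spans, read as the ±2σ span:
σ_m = range_fraction·n/4. Movement is habitat-weighted: kernel weights
toward destination j are multiplied by max(1 − bm_j/K_j, 0.01) and rows
renormalized. At any spatially uniform state this factor cancels, so it
leaves the unfished and no-farm baselines untouched; around farms it
lets the tripled K draw in and retain biomass until relative densities
equalize (an ideal-free distribution), while the 0.01 floor keeps a
residual exchange so full patches still spill over. A purely static
kernel was tried first and rejected: protected patches could not hold
biomass against diffusion, and the refuge effect all but vanished.

**Growth.** Length is von Bertalanffy; weight-at-age advances by the
allometric increment scaled by (1 − bm/K), clamped at zero when a patch
transiently exceeds K (fish stop growing; they do not shrink). Because
fish carry their weight with them, movement transports both numbers and
biomass and re-derives per-patch mean weight; the plus group merges by
biomass-weighted mean.

**Recruitment.** Larvae are produced in proportion to spawning biomass
(ages ≥ age_mature), pooled, and settle uniformly — larval dispersal is
deliberately well mixed so spatial signal comes from adult movement.
Settlers pass a per-patch Beverton–Holt bottleneck with capacity
recruit_steepness·K_recruit. `K_recruit` stays at the calibrated
baseline everywhere, farms included: farm structure raises the *growth*
ceiling (K_farm = 3·K_patch), not nursery capacity. Letting the farm
multiplier act on recruitment capacity as well turns farms into
recruitment factories and makes catch gains grow almost linearly in
farm area, which is not the intended mechanism.

**Carrying capacity** is defined as the unfished equilibrium: a target
system biomass (1000 units) is prescribed and uniform per-patch K is
rescaled until the full no-fishing dynamics equilibrate at the target
(exact in one rescale by linearity; verified to 1e-6).

## Fishing

Selectivity is logistic in length around a legal length. Catch and
survival follow the Baranov equation with fishing and natural mortality
in a single combined exponential, so no death-ordering artifact exists;
the farm fitness multiplier scales M inside farm patches only.

Effort is an aggregate (sum of per-patch F at catchability 1),
gravity-allocated each year in proportion to fishable (selectivity-
weighted, non-farm) biomass. Farm patches are closed; their effort share
is redistributed over the open patches with the aggregate conserved —
the 1/(1−P_farm) inflation written as a gravity reallocation, since
literal multiplication by raw biomass neither conserves effort nor has
consistent units.

**Strong management** holds the aggregate effort fixed at the value
maximizing equilibrium catch of the no-farm system (grid search over
mean F in [0, 1], 21 points, golden-section refinement). **Weak
management** is myopic open access: each year a bounded 1-D search sets
aggregate effort to maximize that year's profit, price·C(E) − cost·E,
with no anticipation of stock effects.

## Farms

A design specifies the occupied fraction (0–40%), the layout (one
contiguous block, or 5-patch clusters placed with even wrapped spacing),
attraction A ∈ [1, 15], the K multiplier (3), the natural-mortality
multiplier (0.9/1.0/1.1 in the shipped sweeps), and the zone of
influence, defaulting to patches within ⌈2σ_m⌉ of a farm. Attraction
widens the kernel's Gaussian toward farm destinations for ZOI residents:
weight exp(−d²/(A·2σ_m²)). The printed form of this modification is
ambiguous between widening the exponent and multiplying the weight; the
widening reading is implemented because it matches the typeset formula,
degrades gracefully (A has no effect on a sessile species and caps the
farm preference at the flat-kernel limit), and its alternative — a
direct ×A on the weight — over-concentrates the stock at high A
(equilibrium catch losses several times larger than the widening
reading produces). Retention is emergent (attraction + raised K +
habitat-weighted movement), not a separate parameter.

Farm scenarios start from the converged no-farm (BAU) equilibrium,
stamp the farm on instantaneously, and run to a new equilibrium
(relative annual change of biomass and catch < 1e-6 for 10 consecutive
years; cap 500 years). The stage order within a year — movement,
growth, recruitment, effort + harvest, aging — is frozen; equilibrium
ratios are insensitive to rotations of the cycle but transients (e.g.
recovery times) are not.

## Default fixture

No real stock is parameterized, so the defaults are generic teleost
values chosen once and shipped as the reference conditions:

| parameter | value | note |
|---|---|---|
| L∞, k, t0 | 100, 0.2/yr, 0 | generic growth curve |
| b₁, b₂ | 3, 1e-5 | cubic weight–length |
| M | 0.2/yr | typical demersal teleost |
| max age / maturity | 20 (plus group) / 4 yr | |
| legal length | L(3) ≈ 45.1 | gear leads maturity by one year |
| fecundity | 2 larvae per unit SSB | Beverton–Holt steepness ≈ 0.6 |
| recruit_steepness | 0.2 | BH capacity per patch = 0.2·K |
| range_fraction | 0.08 (σ_m = 2) | low-to-moderate mobility, home range comparable to a farm cluster |
| price / cost | 1 / 1.1 per effort | open access depletes well below B_MSY |
| selectivity steepness | 0.25 per length unit | ~knife-edge over ±10 length units |

With these values the MSY search lands at aggregate effort ≈ 47.7
(mean F ≈ 0.48), B_MSY/B₀ ≈ 0.38, and the open-access equilibrium sits
well below it — a depleted, high-value fishery. The free constants
(fecundity, maturity/legal schedule, mobility, cost) were calibrated
against the qualitative and quantitative equilibrium patterns the model
is meant to exhibit — interior MSY, refuge-driven biomass gains,
layout-dependent catch gains — and then frozen; they are configuration,
not code.

## What the defaults do and do not show

Passing sweeps on this fixture demonstrate the *mechanisms* — refuge
buildup, spillover, attraction-driven trapping, design trade-offs — for
one plausible life history. They do not show that any real farm will
benefit any real fishery: the generator has no environmental
stochasticity, no seasonality, a 1-D seascape, uniform larval dispersal
and a single species. Recovery times in particular depend on the frozen
stage order and the instantaneous-introduction protocol.

## Numerical choices

- Convergence: 1e-6 relative over a 10-year window (500-year cap);
  unfished calibration uses 1e-10 (3000-year cap).
- MSY search: coarse grid then bounded Brent; a non-convergent candidate
  scores zero catch with a warning.
- Open-access search: bounded Brent on [0, 300] aggregate effort with
  xatol 0.03; effort 0 is returned whenever maximum profit is
  non-positive.
- Selectivity logistic exponent clipped at ±700 to avoid overflow at
  extreme steepness.
- Division by zero in weight re-derivation guarded by keeping the prior
  weight where a patch-age cell is empty.

## Known limitations

- The worst-case catch loss under strong management at attraction 15 is
  ≈10% on this fixture; stronger attraction formulations (weight
  multiplication) push it past 40% — the two readings of the attraction
  modification bracket a wide range, and empirical aggregation data
  would be needed to pin it down.
- Open access is memoryless profit maximization; fleets with entry/exit
  inertia would overshoot and oscillate where this model steps directly
  to the myopic optimum.
- Effort has no travel cost and no spatial friction beyond gravity
  allocation.
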