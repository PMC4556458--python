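# Methods

## Projection model

Populations are projected with annual stage-classified matrices over DBH size
classes: a first class of 5–9.9 cm, 2.5 cm classes thereafter, and an
open-ended absorbing top class (its upgrowth is structurally zero). The state
of a species stacks merchantable (M) and unmerchantable (UM) blocks of equal
length; merchantability is an irreversible label that changes only when a
merchantable tree advances a class, with probability `x_i` for the advance
out of class *i*. `x` is undefined for the first class (a class-1 advance
keeps merchantable status) and is estimated, where only merchantable-share
data exist, from successive per-class merchantable proportions as
`x_i = max(0, (p_i - p_{i+1}) / p_i)`. An alternative estimator (inverting
the stationary class-share distribution) gives the same values whenever the
shares are themselves stationary, because the stationary share of class i is
the running product of `(1 - x_j)`; the ratio form is the default since it
needs no stationarity assumption.

Survival `S` and upgrowth `G` enter the matrix in the standard Lefkovitch
layout: diagonal stasis `S - G`, subdiagonal advance `G` (validation requires
`S >= G`). Fertility is per capita, equal for merchantable and unmerchantable
parents, and all recruits enter the first *merchantable* class — the model
creates defects only by advancement, so the UM block has no inflow below
class 3 and its first two classes decay to zero asymptotically. A
consequence used throughout the fixtures: the within-class merchantable
shares a stand can hold stationary are the cumulative defect-survival
products normalized to 1 in class 1.

Populations are continuous (fractional trees/ha); matrix projection is
expectation-based and no rounding is applied.

## Density-dependent recruitment

Each year the fertility row is scaled by the complemented Weibull multiplier
`exp(-(Na/b)^shape)` with shape 6 by default. The printed form of this
regulation does not fix how `b` relates to the carrying capacity `K`, so the
package sets `b = K`: the multiplier is 1 at an empty stand, barely responds
far from capacity (0.985 at `Na = K/2`), falls to `1/e` exactly at `K` and is
below 0.01 at `2.15 K`. Both `b` and the shape are overridable. Only
recruitment is regulated; survival and growth are density-independent.

`Na` is, per species, its own total density with `b` tied to its own `K`
(default), or — in grouped mode — the summed density of all modeled species
with `b` tied to the overall `K` (sum of species `K`s unless overridden),
the same stand-level multiplier applied to every species' fertility row.

Carrying capacities come from stem-mapped plots: a square window (default
100 m, step 10 m, flush-right placements included) is swept over the plot
and `K` is the maximum density any placement contains. Species-specific
window maxima occur in different subplots, so they are rescaled
proportionally to sum to the all-species maximum.

## Harvest events

Harvests occur at the start of years 0, c, 2c, … (first harvest on the
initial stand), before that year's projection step; this order is pinned by a
regression test because reversing it changes results. A class is eligible if
its *lower bound* is at or above the MCD (conservative and reproducible,
since class membership of the exact MCD is otherwise ambiguous). The
intensity applies to the eligible basis — merchantable stems under high
seed-tree quality, merchantable plus unmerchantable under low — but removals
are always drawn from merchantable trees only, capped at availability, and
allocated across eligible classes proportionally to abundance (a
largest-first mode is available). The minimum commercial density is an
eligibility threshold (species with less merchantable density above the MCD
are skipped), not a retained floor; a floor interpretation can be emulated
by lowering intensity.

Per-tree volumes use a form-factor cylinder: volume = 0.7 x basal area x
commercial height, with commercial height saturating in DBH
(`h_max * dbh / (dbh + h_half)`, default 25 m and 15 cm). Per-species
coefficients are overridable; the defaults give single-tree volumes of
~1–3 m³ at 50–70 cm DBH and stand-level merchantable stocks of tens of
m³/ha, the right order for floodplain timber stands. When a volume cap is
set, the allowance per harvest is `cap x cycle`; if the offered volume
exceeds it, all species' removals are scaled by one common factor.

Residual stand mortality is a tree-number ratio (trees incidentally killed
per tree harvested) applied to everything left standing, indiscriminate of
species, class and merchantability — each cell loses the same fraction, with
kills truncated at availability. Field observations of such damage are
reported as basal-area ratios; the fixtures convert the timber-species
basal-area ratio (0.13 m² killed per m² extracted; palms and non-timber
species are not modeled populations) into a tree-number default using the
demo stand's mean harvested-tree and mean residual-stem basal areas, giving
~0.85 trees killed per tree harvested. The full observed damage table,
including the 0.62 all-groups total, ships as `OBSERVED_DAMAGE_TABLE`; the
ratio is a plain config value and can be set to any observation.

## Post-harvest effects

For a fixed window (default 10 years) after every harvest, species follow
modified matrices: upgrowth of juvenile classes (lower bound <= 20 cm, so the
class containing 20 cm is juvenile) scaled by a species factor, adult
upgrowth by another (default 1), fertility by a recruitment factor (above 1
only for species with an observed post-harvest recruitment boost). Survival
is unchanged. Effects are stand-wide per species (matrix state carries no
cohort identity) and windows refresh rather than stack — a new harvest
restarts the clock, so a cycle no longer than the duration keeps the modified
matrix active permanently. Scaled upgrowth is clipped at survival with a
warning.

## Simulation outputs and indicators

Trajectories record pre-harvest states, so `N_0` and `N_120` of
`lambda_H = (N_120/N_0)^(1/120)` are both pre-harvest densities.
Compensatory recruitment is the smallest constant yearly planting into class
M1 that achieves `N_120 >= N_0` per species, found by bisection (tolerance
1e-3 recruits/ha/yr; upper bracket 10 x the species' initial class-1 density
+ 1, reported as an error if insufficient rather than silently capped).

Annualized yield of harvest k (k >= 2) is its volume divided by the cycle;
the first harvest removes stock of unknown accrual period and has none. Mean
AY averages harvests strictly inside the 120-yr window. Fifth-harvest AY is
defined on the harvest sequence itself; for cycles above 30 yr the fifth
harvest falls beyond year 120, so sweep simulations extend to `4 x cycle + 1`
years while lambda_H and mean AY stay evaluated on the 120-yr window. The
ranked indicator sums the rank of mean AY and the rank of lambda_H (rank 1 =
best, ties averaged) and minimizes the sum; lambda_H is the all-species rate
for stand-level ranking and the species' own for species-specific ranking.
Ties break toward gentler regimes: lower intensity, then higher MCD, then
longer cycle. The factorial criteria grid (4 cycles x 5 intensities x 5 MCDs
x 3 minimum densities x 2 seed-tree qualities x 2 cap settings) enumerates
1200 regimes in documented lexicographic order; the set of harvested species
is a further, config-driven axis rather than a hard-coded count.

## LTRE

The fixed-design life table response experiment evaluates eigenvalue
sensitivities `s_ij = v_i w_j / <v, w>` at the mean of the treatment and
reference matrices and reports contributions `(a_ij^T - a_ij^R) s_ij`,
grouped by demographic role (stasis, growth, defect development, fertility)
and class. Sensitivities are reported for structurally zero entries too (the
classical convention); the grouped output labels them. Eigenpairs come from
dense eigendecomposition with the left vector scaled so `<v, w> = 1`;
reducible or defective inputs raise rather than return meaningless vectors.

## Synthetic data

No fitted matrices for the study system are published, so the generator
produces species with the *structure* the model assumes rather than any
species' actual rates. Three profiles span the observed contrasts:

- **fast** (lambda calibrated into 1.025–1.04): high survival, fast growth,
  ample recruitment, mild defect accumulation; recovers stock between
  harvests.
- **slow** (0.992–0.998): very high survival, slow growth, strong defect
  accumulation with size; yields decline but the population roughly holds.
- **pioneer** (0.986–0.992): high juvenile growth, near-zero closed-canopy
  fertility (calibrated to the band's small values), a 2x post-harvest
  recruitment boost; its stable structure is cohort-like (mass concentrated
  at large sizes), matching long-lived light-demanding canopy species.

Survival rises from 0.973 to ~0.985 with size with senescence in the two
largest classes (without it, mass accumulates unrealistically in the open
top class whenever lambda is close to top-class stasis). Fertility is
proportional to basal area above a 30 cm reproductive threshold, with its
scale solved by Brent root-finding so the dominant eigenvalue hits the
profile's band exactly; small seeded jitter on S and G differentiates
replicate species. Defect transitions derive from a declining
merchantable-share curve via the ratio estimator above.

The demo stand (420 trees/ha; slow 45%, fast 35%, pioneer 20%) is placed at
each species' stable stage distribution, representing the average,
near-equilibrium surveyed stand: without harvest, class structure and
merchantable proportion then stay constant (up to density regulation), so
simulated shifts are attributable to harvest. A geometric reverse-J
generator (decay 0.82/class, monotone by construction) is the `make_stand`
default for tests that need guaranteed shape properties. Stem maps are
uniform or Thomas-process clustered point patterns.

What the generator does *not* emulate: spatial structure within stands,
temporal (good/bad year) variation in vital rates, observation error, and
between-plot heterogeneity. Passing tests therefore demonstrate the model's
internal consistency and qualitative behavior under realistic parameter
magnitudes, not predictive accuracy for any real stand.

## Numerical choices

- Eigenanalysis: `numpy.linalg.eig`; the dominant pair is validated (real,
  simple, `<v, w>` bounded away from zero); a spectral-radius helper serves
  calibration on reducible (fertility-free) matrices.
- Problem sizes: species use 26 classes (5 cm to a 70+ cm top class); the
  full sweep is 1200 regimes x 3 species at 120–161 yr, about 10 s.
- Bisection tolerances: 1e-3 recruits/ha/yr (compensatory recruitment),
  1e-10 on the fertility scale (calibration).
- Degenerate inputs: empty stands project to empty; merchantable proportion
  of an absent species is NaN; a zero-volume offer under a cap is simply not
  binding; harvests of species sets excluding everything reduce to pure
  projection.

## Known limitations

- Vital rates are time-invariant apart from the post-harvest window and
  recruitment regulation; no stochasticity or environmental covariates.
- Damage, allometry and post-harvest multipliers are stand-level constants,
  not size- or gap-structured.
- The minimum-density rule uses merchantable density above the MCD;
  jurisdictions differ on the reference population.
- Compensatory recruitment assumes planted recruits follow the same matrix
  as natural ones from year 1.
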