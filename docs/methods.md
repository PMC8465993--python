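# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of the package.

## Pipeline overview

The pipeline couples a non-spatial demand module (Markov projection of class
areas) with a spatial allocation module (iterative competition of classes for
cells over logistic suitability surfaces), then assesses four ecosystem
services on the resulting maps and grades them into ordinal importance
levels. All stages operate on rectangular grids with square cells (default
1 km; the analysis grid size of the original application is not fixed by the
data, so cell size is a parameter everywhere). Areas are km²; NoData
propagates — a cell masked in any input is masked in every product.

## Demand: Markov projection with scenario modifiers

Transition probabilities are the row-normalized transfer matrix between two
observed dates; a class absent at the first date gets an identity row (it
cannot be observed transitioning) with a warning. The step length equals the
observation spacing (default 5 years); yearly demand for the allocator is
linearly interpolated between step nodes. Scenario modifiers multiply
off-diagonal row entries (outflows; 0 freezes a protected class) or
off-diagonal column entries (inflows; >1 accelerates a growing class), after
which rows are renormalized, so the matrix stays stochastic and total area is
conserved exactly at every projected year.

The default scenario freezes wetland outflow. This keeps demand consistent
with the allocation default of elasticity 1 for wetland: a class whose cells
can never convert away cannot meet a shrinking demand, and the allocator
treats that combination as an infeasibility error rather than silently
violating either constraint.

## Suitability: stepwise logistic models

Per class, a binary (one-vs-rest) logistic regression is fitted by maximum
likelihood (statsmodels) on drivers standardized to zero mean and unit
variance over unmasked cells. Forward-stepwise selection uses Wald tests
with entry p < 0.05 and removal p > 0.10 (the common SPSS defaults);
iteration stops at a fixpoint, with cycle detection. A class occupying less
than 1 % or more than 99 % of cells is rejected as degenerate.

When the ML fit fails (perfect separation, singular Hessian), a
Newton–Raphson fit with a tiny ridge penalty (1e−6, intercept unpenalized)
takes over. Under separation the Wald statistic collapses (the Hauck–Donner
effect), so a quasi-infinite standardized coefficient (|β| > 15) is treated
as significant in the selection step; the fitted surface then classifies the
separable class perfectly, which is the behaviour one wants from the
admission test.

ROC AUC is computed in-sample by the Mann–Whitney rank formulation (ties
count ½) — there is no holdout protocol at this stage; AUC is invariant
under monotone transforms of the scores.

## Allocation

Each unrestricted cell receives the admissible class maximizing
`TPROP_u = P_u + ELAS_u·[incumbent] + ITER_u`. Admissibility requires the
conversion rule `allowed[current → u]`, and cells of a class with elasticity
1, or under the restricted mask, may only keep their class. Ties break
toward the lowest class code, making allocation deterministic.

The balancing term ITER starts at 0 each year and is updated additively,
`ITER_u += gain_u · (demand_u − allocated_u)/total_area`. A fixed gain is
far too slow: yearly demanded changes are of order 10⁻³ of total area, and a
fixed step of that size cannot overcome O(0.1) suitability differences
within a reasonable iteration budget. The gain is therefore adaptive per
class — base step 0.05, multiplied by 1.3 while the residual keeps its sign,
halved on overshoot, clipped to [1e−6, 10] — which converges in tens of
iterations on 100×100 landscapes. Convergence is declared when every class
residual is within `tolerance_frac` (default 0.001) of total area;
non-convergence raises an error carrying the last residuals.

Demand feasibility is checked up front: each class's demand must lie between
the area locked into it (elasticity-1 incumbents, restricted cells) and the
area that could ever carry it under the conversion rules.

Default elasticities — wetland 1.0 (strictly protected water bodies),
artificial 0.9, forest/grassland 0.6, cultivated 0.4, other 0.3 — express
typical conversion resistance for this kind of landscape; they are
configuration values, not calibrated constants.

## Ecosystem services

* **Water conservation**: per-cell `(P − R − ET)` in mm times cell area
  (1 mm over 1 km² = 1000 m³). Surface runoff has no standard raster source
  at this level of abstraction, so R is modelled as a per-class runoff
  coefficient times rainfall (defaults: wetland 0.05, forest 0.15, grassland
  0.25, cultivated 0.35, other 0.45, artificial 0.60). Negative cells are
  allowed in the total TQ but floored at zero when grading.
* **Soil conservation** (USLE): `A_c = R·K·L·S·(1−C)`, returned with the
  potential (`A_p = RKLS`) and actual (`A_r = A_p·C`) erosion so the identity
  `A_c = A_p − A_r` holds exactly per cell. The slope-length factor L is not
  flow-path traced; it defaults to the unit-plot value 1 and accepts an
  override raster. A convenience helper derives the steepness factor S from
  slope via McCool's piecewise relation.
* **Sand fixation**: `S_WS = NPP_mean · K_s · F_q · D`, a dimensionless
  capacity index. The climatic factor `F_q` sums `u³·(ETP−P)/ETP·d` over
  months, the moisture-deficit ratio clamped at 0 (wind erosion inactive in
  humid months) and months with ETP ≤ 0 contributing nothing. ETP uses the
  quadratic `0.19(20+T)²(1−r)`, clamped to 0 at or below −20 °C where the
  quadratic would otherwise rise again. Wind speed is moved between
  measurement height (default 10 m) and the 2 m reference by the 1/7-power
  profile law. Slope enters through the roughness factor `D = 1/cos θ`.
  USLE erodibility (K) and the wind-erosion soil factor (K_s) are distinct
  inputs and are named `erodibility_k` / `soil_wind_k` to avoid the symbol
  collision.
* **Biodiversity**: a rectilinear envelope model. Per species with ≥ 5
  occurrence points, each driver gets a [5th, 95th]-percentile envelope of
  its values at the occurrences; a cell's species score is the fraction of
  drivers inside the envelope, and the output is the protection-weighted
  mean over species. This is deliberately the simplest member of the
  climate-envelope SDM family — transparent and exactly testable.

Every calculator is deterministic and cell-local, so results are invariant
under tiling and recombination of the raster.

## Importance grading and encroachment

Grading sorts unmasked cells by service value (descending, ties by row-major
index, negatives floored at 0) and cuts the cumulative-share curve at
configurable thresholds (0.35, 0.65, 0.85): the minimal prefix reaching 35 %
of the service total is Very Important, and so on; an all-zero raster grades
entirely Common with a warning. Four levels are used throughout, matching
the reporting convention of the graded statistics tables. The thresholds are
a package default — grading guidelines delegate them to policy documents —
and the prefix rule guarantees the levels partition the landscape and that
raising a cell's value never lowers its level.

Combined importance is the per-cell maximum level across services
(idempotent, order-invariant). Encroachment accounting takes the cells newly
converted to artificial surface between two maps and, per cell, collects the
services whose importance there is Moderate or higher; severity is the
cardinality of that set (1 → Moderate, keyed by the service; 2 → Important,
keyed by the pair; ≥3 → Very Important, keyed by the combination), and
acreages accumulate per combination with severity totals that are exact row
sums.

## Synthetic-data design

The generator emulates the statistical structure the pipeline assumes, not
real geomorphology. All fields derive from seeded, named random streams
(stable CRC-based substream keys), so every product is bit-reproducible from
one integer seed.

* **DEM**: Gaussian white noise smoothed with a Gaussian kernel
  (radius = `spatial_smoothness` cells). The amplitude applies before
  smoothing, so field variance shrinks monotonically with smoothness and the
  σ → ∞ limit is a constant plain.
* **Drivers**: temperature follows the standard atmospheric lapse rate
  (−0.0065 °C/m) plus independent smoothed noise; rainfall couples weakly
  and positively to elevation; settlement/road/river locations are random
  points and random-walk polylines, with distances from an exact Euclidean
  distance transform; population density decays exponentially with
  settlement distance times a log-normal noise field.
* **Land use**: sampled per cell from a multinomial logit over the true
  per-class coefficients applied to standardized drivers. A multinomial
  (rather than six independent binaries) guarantees the classes partition
  every cell. The second-date map converts the non-artificial cells nearest
  settlements to artificial surface — deterministic urban accretion at the
  fringe.
* **Climate**: sinusoidal seasonal cycles (July peak) with month-level
  noise, spatially uniform — the scene stands in for a single
  climate-station region; humidity clipped to [0,1], precipitation floored
  at 0.
* **Species occurrences**: sampled proportional to a smooth [0,1] habitat
  template, with small integer protection weights.

**Identifiability.** The default true-coefficient matrix gives every class
two drivers with |β| ≥ 1. One-vs-rest refits of a multinomial map are
systematically biased on drivers shared between classes (attenuated when the
sharing classes load the driver with the same sign, inflated when opposite),
and the bias is severe for heavily skewed fields. The defaults therefore
(a) give temperature and rainfall substantial variation independent of the
DEM so the stack is well-conditioned, (b) share strong drivers only with the
same sign and only on low-skew fields, and (c) make the skewed population
density strong for a single class. With eight drivers and twelve strong
slots, four drivers must be shared; this is the arrangement under which the
recovery experiment (signs and magnitudes within ±0.5 at 10⁴ cells) is
statistically attainable.

**What passing tests do and do not show.** Synthetic landscapes are
spatially autocorrelated but stationary, drivers are nearly Gaussian, class
membership is exactly multinomial-logit in the drivers, and there is no
spatial autocorrelation in the residual class noise. Real interpreted
land-use data violate all of these (patch contiguity, classification error,
unmeasured drivers), so in-sample ROC values and recovery margins here are
optimistic relative to field data; what the tests establish is that each
mechanism — estimation, allocation, accounting — is implemented correctly,
not that any particular real-world accuracy will be achieved.

## Problem sizes and numerical choices

Simulation-based tests use 100×100 grids (10⁴ cells) for fitting/recovery
and 50×50 for allocation properties; the recovery experiment uses 20 seeded
replicates. Logistic fits cap Newton iterations at 200 (ML) / 100 (ridge);
linear predictors are clipped at ±30 (fits) and ±700 (surfaces) before
exponentiation. Allocation tie-breaks, the grading tie rule (row-major), and
the stable sorts behind them make every pipeline product deterministic for a
given seed. Two-decimal rounding is applied only at the reporting layer
(CSV tables), never inside computations.

## Known limitations

* No projected-CRS handling or vector geometry; rasters are plain grids
  (ESRI ASCII), and GeoTIFF is out of scope.
* Runoff and the USLE L factor are abstractions (per-class coefficient;
  unit plot) — adequate for grading-level comparisons, not hydrological
  modelling.
* The biodiversity model is an envelope SDM; it has no occurrence bias
  correction and no interaction structure.
* In-sample ROC overstates out-of-sample discrimination; no holdout or
  spatial cross-validation is provided.
* Demand is a first-order Markov chain; economic couplings and
  region-partitioned demand are not modelled.
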