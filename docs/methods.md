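# Methods

## Scope and design

`paddysalt` couples three daily-time-step components: a ponded
tipping-bucket soil water balance with chloride transport, a logistic
salinity-stress formulation acting on transpiration and photosynthesis, and
a compact radiation-use-efficiency (RUE) rice growth engine. It is built to
study the *relative* response of rice genotypes to salinity — stress-factor
shapes, yield ordering across salinity levels, parameter sensitivity — not
to re-predict any particular field trial.

## Salinity representation

All salinity is the electrical conductivity of the soil solution
(EC, dS m⁻¹). Two conversion constants live in one configurable type
(`ConversionConstants`) and are never hard-coded at call sites:

* osmotic tension: `OSKPA = 40.55 · EC` (kPa per dS m⁻¹). Osmotic
  potential is represented as a *positive tension* added to matric tension,
  so no signed-potential bookkeeping is needed anywhere.
* chloride bridge: `EC = [Cl]/640` with [Cl] the thickness-weighted mean
  solution chloride concentration (ppm) over the root zone. The same
  constant is used in the forward direction to set the chloride load of
  irrigation water (ppm = 640 · EC_iw), which makes the conversion
  self-inverting: a profile steadily flushed with water at EC_iw settles at
  a root-zone EC of exactly EC_iw (verified by test). An alternative
  NaCl-mass-fraction convention ([Cl] ≈ 0.6066 · TDS) can be had by
  overriding the chloride constant.

The stress factor `FS = 1/(1+exp(a·(EC−b)))` is evaluated in log-sum-exp
form for numerical stability. Note FS(0) < 1 by construction (≈0.84 for
IR64 transpiration): even fresh water carries a residual factor. The
faithful behaviour is the default because the factor's absolute level is
part of the genotype parameterization; `normalize=True` rescales by FS(0)
for users who want an exactly unstressed control. Which convention the
original implementations used is not documented; both are provided.

Sparse measured EC series are linearly interpolated to daily values;
outside the measured span the nearest measured value is held constant
(extrapolating the line could produce negative or unbounded EC).

## Soil water and chloride

The profile is a stack of fully mixed layers (default: 4 × 200 mm,
θ_sat/θ_fc/θ_wp = 0.50/0.35/0.15, a generic puddled clay loam) under a
bunded pond (default bund 100 mm, design percolation 5 mm d⁻¹, typical of
puddled paddies). The daily cascade: surface additions fill the pond, the
excess above the bund runs off; the pond percolates into the top layer at
the design rate; each layer spills water above field capacity downward the
same day; bottom spill is drainage. Evaporation is taken from the pond
first, then from the top layer down to wilting point; transpiration is
extracted over the root zone proportionally to plant-available water above
wilting point and capped by it. These orderings are the simplest defensible
contracts; nothing in the formulation depends on them strongly under
continuous flooding, where the pond supplies percolation and evaporation.

Chloride moves advectively with every water flux at the fully mixed source
concentration (mixing-cell transport, the standard companion of a tipping
bucket; no explicit diffusion term). Three design choices deserve note:

* **Runoff carries the mixed pond concentration.** A salt-free-runoff
  variant was tried and rejected: whenever the pond overflowed it trapped
  applied salt, and sustained over-irrigation at EC_iw drove the soil
  solution to about twice EC_iw, breaking the self-inversion property
  above.
* **The transpiration stream carries chloride** at the source layer's
  concentration (an explicit plant-uptake term in the ledger). With
  salt-excluding roots the root zone would concentrate without bound under
  steady transpiration; advective uptake keeps the irrigation→soil EC loop
  consistent and is the convention under which the flushing steady state
  equals the irrigation EC. Shoot ion content is not tracked — the stress
  factor is the model's proxy for accumulated toxicity.
* **Evaporation carries no salt**, so it concentrates the remaining
  solution (the reason a real flooded season sits above the irrigation EC).

Both ledgers are closed *every step* inside `step_water`/`step_salt`
(tolerances 10⁻⁶ mm and 10⁻⁹-relative kg ha⁻¹) and a violation raises
rather than accumulating.

Matric tension uses the Campbell retention form
`τ = τ_e (θ/θ_sat)^(−shape)` (defaults τ_e = 0.1 kPa, shape = 5) and is
zero for a saturated layer or under ponded water — so under continuous
flooding crop water stress is driven by the osmotic term alone, which an
integration test asserts.

An optional management rule (`max_ec_manager`) replaces saline irrigation
with fresh water whenever root-zone EC reaches a threshold, emulating how
imposed-salinity treatments are capped in practice. It is off by default.

## Crop engine

Phenology: DVS 0→1 (transplanting to flowering) at `dvr_veg` per °C-day
above T_base = 8 °C, DVS 1→2 (maturity) at `dvr_rep`; a day crossing
DVS = 1 splits its thermal time between the two rates. Defaults
(8×10⁻⁴, 1.5×10⁻³ °Cd⁻¹) put flowering near day 65 and maturity near day
100 in tropical conditions; treatment-specific rates are *inputs*
(derivable from observed dates with `derive_dev_rates`), which is how any
salinity effect on phenology enters — it is not modelled mechanistically.

Assimilation is an RUE core rather than leaf-level photosynthesis with
canopy integration: gross growth
`= RUE · 0.5·Rs · (1−e^(−k·LAI)) · FS_pn · PCEW` (g m⁻² → ×10 kg ha⁻¹),
with RUE = 2.2 g MJ⁻¹ PAR, k = 0.6, SLA = 0.0022 ha kg⁻¹ — generic
irrigated-indica values. The salinity factor enters multiplicatively
exactly as the logistic formulation prescribes, which is the formulation's
stated intent for stage-driven RUE models. PCEW is the actual:potential
transpiration ratio (1 when potential is zero). Potential transpiration is
the canopy-intercepted share of Priestley–Taylor reference ET (α = 1.26,
R_n = 0.75·Rs, γ = 0.066 kPa °C⁻¹, λ = 2.45 MJ kg⁻¹); the soil share is the
complement. The drought factor is 1 below 30 kPa total (matric + osmotic)
tension and falls linearly to 0 at 1500 kPa (wilting-point order). The
multiplicative composition T_act = T_pot · drought · FS_tr, further capped
by soil supply, is implemented literally; how the original engines couple
supply and demand under combined tension is not documented, and this is the
plainest reading.

Partitioning is linear interpolation in a DVS-keyed table (leaf/stem
early, panicle-only after DVS 1.2; knots sum to 1, so interpolants do
too); after flowering green leaf senesces to dead leaf at 0.0125 d⁻¹.
Yield is the panicle pool (WSO) at maturity; WAGT is the sum of all
above-ground pools. Spikelet sterility, harvest-index stress, nitrogen and
leaf rolling are out of scope.

A season run is fully deterministic and raises an explicit error if the
weather table ends before DVS reaches 2.

### Cross-mode consistency

`measured` and `simulated` EC modes share the entire loop except the EC
source. Their consistency is checked two ways: (a) at the soil level, the
flushing steady state equals the irrigation EC (no evaporation); (b) at the
crop level, replaying a simulated-EC season's realized daily EC series
through measured-EC mode reproduces its yield. A naive third form —
constant measured EC versus the simulated steady state at the same
irrigation EC — is *not* expected to agree, because evaporative
concentration keeps a real flooded season's soil EC above the irrigation
EC; this is physics, not error.

## Calibration

Stress parameters are fitted by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, positivity bounds, start a = 0.2, b = median
EC). Rates should be control-normalized fractions; raw rates can be
normalized by the lowest-EC mean first (`normalize=True`). Flat curves are
flagged `converged=False` (no information about the inflection), as are
fits with non-finite covariance or a pinned parameter. Because the slope
often does not differ between processes, `fit_shared_slope` offers a joint
two-curve fit with a single shared `a`; both free and shared fits are
first-class. Noiseless synthetic curves reproduce the shipped genotype
parameters to < 10⁻⁶; with 5 % multiplicative noise and 12 points, b is
recovered within ±10 % in ≥95 of 100 seeded replicates (test-pinned).

Development rates are reciprocals of the accumulated thermal time between
observed stage dates; a round-trip test confirms the simulated flowering
and maturity days land within one day of the observations.

## Agreement statistics

RMSE and mean-normalized RMSE (%, the *root* form — the name says
normalized root mean squared error), Willmott's (1981) index of agreement
with the standard sum-form denominator
`Σ(|S−μ_O|+|O−μ_O|)²` (a difference-form variant is available behind
`typeset_variant=True` for forensic comparison only), OLS of simulated on
observed, and the two-sided Welch test (unequal variances,
Welch–Satterthwaite df; p = 1 by convention for the degenerate
zero-variance equal-mean case). All four are cross-checked against
brute-force textbook formulas to 10⁻⁶ in the tests. The conventional
"good model" reading — slope→1, intercept→0, R²→1, p > 0.05, RMSE within
the observed SD — is packaged as `agreement_criteria` predicates with
configurable thresholds.

## Sensitivity protocol

One parameter at a time, multipliers ±1..6 of its SD, crossed with
salinity levels (default 1, 4, 8, 12 dS m⁻¹; 1 dS m⁻¹ stands for the
fresh-water control range) and weather years; each cell is one
deterministic season run with the level imposed as a constant daily EC
pattern identical across years. Greenhouse SDs of the parameters are not
available, so the default SD is 5 % of the base value — a package default,
clearly not a measured quantity. Perturbations that would push a parameter
non-positive are dropped with a warning.

Variance decomposition is balanced two-way ANOVA with method-of-moments
components (negative estimates truncated at zero, shares normalized to
100 %). Under the balanced one-at-a-time design this coincides with a
random-effects decomposition while needing no mixed-model machinery.
`decompose_outputs` treats the whole parameter-setting factor against the
environment; `per_parameter_decomposition` scores each parameter within its
own slice. Directional results (test-pinned): yield rises with b_tr (a 5 %
increase of b_tr raises mean yield across environments) and falls with
a_tr.

## Synthetic fixtures

All generators are pure functions of (profile, seed). Weather: annual
sinusoid plus Gaussian noise for temperatures and radiation (tropical
defaults give mean daily maxima in 28–32 °C and ~18 MJ m⁻² radiation),
seeded wet-day draws with exponential depths for rainfall. Greenhouse
curves: logistic truth on an EC grid 0–20 dS m⁻¹ with multiplicative
Gaussian noise. Field observations: WAGT and LAI at the five conventional
sampling stages (28 and 42 days after transplanting, flowering,
grain-filling, maturity) plus yield at maturity, three replicates,
multiplicative log-normal noise (non-negative support, mean-preserving).
What the fixtures do **not** emulate: weather autocorrelation beyond the
seasonal cycle, typhoon/extreme events, sensor drift or logger artifacts,
spatial field heterogeneity, or any salinity–phenology interaction. Tests
passing on these fixtures therefore demonstrate internal consistency and
correct mechanics, not predictive skill on real field data.

## Problem sizes

Default test and demonstration runs use 150-day single seasons on a
4-layer profile, 100×120-day random schedules for the conservation
ledgers, 100 replicates for the noisy-recovery rate, and 2-year × 4-level
sensitivity grids (392 season runs) — sizes chosen so the full suite
completes in seconds while every property is exercised at scale.

## Known limitations

* The RUE engine is deliberately simpler than full leaf-level crop models;
  absolute yields are indicative (fresh-water WAGT lands in the
  8–20 t ha⁻¹ plausibility band by construction of the defaults).
* No nitrogen, no pond biogeochemistry, no upward capillary flow or water
  table; drainage is strictly one-way.
* Chloride uptake by the transpiration stream is a closure assumption, not
  measured plant physiology (see above).
* Salinity affects neither phenology nor partitioning except through
  user-supplied per-treatment inputs.
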