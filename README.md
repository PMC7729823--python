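# paddysalt

Daily-time-step simulation of irrigated rice growing under soil salinity,
for crop modellers and agronomists who need to quantify how saline
irrigation water depresses transpiration, biomass accumulation and grain
yield — and how much of that response is genotype-dependent.

## The model in brief

Soil salinity is carried as the electrical conductivity of the soil
solution, EC (dS m⁻¹). It acts on the crop through two coupled channels:

**Osmotic stress.** The solution's osmotic tension is proportional to EC,

    OSKPA = 40.55 · EC      (kPa),

and is added to the matric tension of the root zone; the total tension
drives a fraction-of-transpirable-soil-water drought factor that reduces
transpiration.

**Ion-toxicity stress.** Daily maximum photosynthesis (pn) and
transpiration (tr) are each multiplied by a two-parameter logistic stress
factor

    FSᵢ = 1 / (1 + exp(aᵢ · (EC − bᵢ))),    i ∈ {pn, tr},

where *b* is the EC at which half the process rate is lost (salinity
*tolerance*) and *a* is the slope at that inflection point (salinity
*resilience*; smaller *a*, more gradual decline). Both are genotype
parameters; sets for IR64, IR29 and BRRI Dhan47 ship with the package
(`paddysalt.GENOTYPES`).

Around this core sit:

* a tipping-bucket layered soil water balance with a ponded (bunded)
  surface layer, in which chloride moves advectively with every water flux
  and root-zone EC is recovered from the mean solution chloride via
  `EC = [Cl]/640` (`simulated` mode); alternatively sparse measured soil-EC
  series are linearly interpolated to daily values (`measured` mode);
* an ORYZA-style radiation-use-efficiency crop engine (thermal-time
  phenology on the DVS scale, Beer-law interception, DVS-keyed
  partitioning, post-flowering senescence), in which FS_tr scales
  transpiration and FS_pn together with PCEW (the actual:potential
  transpiration ratio) scales assimilation;
* calibration: nonlinear least-squares fits of the logistic to greenhouse
  dose-response curves (optionally with a slope shared between processes)
  and development rates from observed phenology dates;
* agreement statistics: RMSE, mean-normalized RMSE (%), Willmott's index of
  agreement, OLS slope/intercept/R², Welch's t-test;
* a one-at-a-time sensitivity protocol (±1–6 SD per parameter × salinity
  levels × weather years) with balanced two-way ANOVA variance components;
* seeded synthetic generators for tropical weather, greenhouse curves,
  irrigation schedules and noisy field observations, so everything runs
  without any external data.

## Worked example

Yield response of IR64 to constant soil-salinity levels under one year of
seeded synthetic tropical weather:

```python
import paddysalt as ps
from paddysalt.run_helpers import constant_ec_runner

runner = constant_ec_runner(n_years=1, seed=42)
ir64 = ps.get_genotype("IR64")
for level in (0.0, 4.0, 8.0, 12.0):
    r = runner(ir64, level, 0)
    wp = ps.water_productivity(r.yield_kg_ha, r.total_transpiration_mm)
    print(level, round(r.yield_kg_ha), round(r.final_wagt),
          round(r.total_transpiration_mm), round(wp, 2))
```

prints

```
level  yield  wagt  transp  WP
    0   6202  12670    369  16.79
    4   3232   6435    208  15.57
    8    704   1563     59  11.85
   12     97    336     14   6.98
```

i.e. final grain yield (kg ha⁻¹), total above-ground biomass (kg ha⁻¹),
seasonal transpiration (mm) and water productivity (kg ha⁻¹ mm⁻¹) all fall
monotonically with salinity: light stress at 4 dS m⁻¹ roughly halves yield
for this moderately tolerant genotype (FS_tr(4) = 0.69, against 0.85 for
the tolerant BRRI Dhan47), while 12 dS m⁻¹ is close to crop failure.

The same pipeline from the shell — generate a noisy greenhouse curve and
recover the genotype parameters:

```sh
paddysalt synth curve --genotype IR64 --noise-cv 0.05 --seed 7 --out curve.csv
paddysalt calibrate stress --input curve.csv
# photosynthesis: a=0.1768  b=10.7408  converged=True
# transpiration:  a=0.2074  b=7.6827   converged=True
```

against true values (a = 0.21, b_pn = 11.17, b_tr = 7.83). Other commands:
`paddysalt simulate --config run.yml`, `paddysalt evaluate --pairs ...`,
`paddysalt sensitivity`, `paddysalt synth weather|schedule|obs`.

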