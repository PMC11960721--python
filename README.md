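# vegniche

Gaussian-niche modelling of forest understory plant community composition,
with shading-height light competition, niche calibration against observed
relevé covers, and a model-evaluation metric suite.

## The problem

The species composition of a forest's herbaceous layer (plants up to
1.8 m) responds to soil-solution chemistry, moisture, temperature, light
at the forest floor and competition among the plants themselves. Given
monthly environmental driver series per soil layer — the kind of output a
biogeochemical forest-ecosystem simulator produces — `vegniche` predicts
the **relative surface cover** of each species in a fixed species list,
calibrates the species' niche parameters so predictions match field
relevés, and quantifies model fit. It is aimed at ecosystem modellers who
couple soil/climate simulations to plant community response.

## The model

Each species is described by a set of fundamental niches. Response to a
driver (soil-solution pH, soil-solution N in mg/L, soil moisture
saturation fraction, or the fraction of above-canopy light reaching the
plant) is a Gaussian curve

    Resp(driver, opt, var) = exp( -(driver - opt)^2 / var )

where `opt` is the optimum and `var` the tolerance (squared driver
units). Temperature acts as a hard window: the response is 1 for
`tmin <= T <= tmax` and 0 outside. Site suitability is the product of the
four Gaussian responses gated by temperature.

Each species has a **rooting depth** (its soil drivers are
thickness-weighted means over the layers its roots reach) and a
**shading height**: taller plants shade shorter ones, reducing the light
available to a plant to `floor_light * (1 - s * C_taller)` with `s` the
shading efficiency (default 0.75) and `C_taller` the summed cover of
strictly taller species. Suitability computed with shaded light is the
plant's competitive strength, and relative covers are
strength-proportional: `cover_i = strength_i / sum_j strength_j`, so
covers are normalized to 1. Because shading depends on covers and covers
on shaded suitability, the within-year solution is a damped fixed point;
growing-season (May–September) monthly suitabilities are averaged, and
the model steps annually.

**Calibration** adjusts species' niche class ranks (optima first, then
tolerances and shading height) one class at a time, re-simulating after
each move, until every species' predicted cover is within 5 percentage
points of observation — mimicking the expert procedure of fixing false
dominants, suppressed dominants and mis-fit sub-dominants, in that order,
within per-species class windows that stand in for literature constraints.

**Evaluation metrics**: normalized average error `NAE = (P̄ - Ō)/Ō`,
normalized root-mean-square error `NRMSE = sqrt(Σ(Pᵢ-Oᵢ)²/N)/Ō`,
zero-intercept 1:1 slope `ΣPO/ΣO²` with standard error and Pearson
correlation, and the Czekanowski community similarity
`CzI = 1 - Σ|P-O| / Σ(P+O)` (quantitative Sörensen; 1 = identical
communities).

The package ships observed/blind/calibrated cover tables for three
northeastern US sugar-maple–beech–yellow-birch sites (HBEF in New
Hampshire; the East Bear and West Bear watersheds in Maine), and a
synthetic driver generator emulating biogeochemical-model output
(seasonal cycle, decadal trend, noise) so the whole chain runs without an
external simulator.

## Worked example

```python
from vegniche import (SyntheticDriverConfig, generate_synthetic_drivers,
                      example_parameter_table, simulate_community,
                      load_cover_pairs, czekanowski)

cfg = SyntheticDriverConfig(start_year=2000, n_years=3, seed=1)
drivers = generate_synthetic_drivers(cfg)
final = simulate_community(example_parameter_table(), drivers, cfg.profile)[-1]
for name, cover in final.covers.items():
    print(f"{name:16s} {cover:6.3f}")

for site in ("HBEF", "EB", "WB"):
    pairs = load_cover_pairs(site)
    print(f"{site:5s} blind CzI {czekanowski(pairs['blind']):.3f}   "
          f"calibrated CzI {czekanowski(pairs['calibrated']):.3f}")
```

prints

```
Fern tall         0.200
Fern low          0.404
Shrub tall        0.003
Herb shade        0.378
Herb light        0.000
Seedling broad    0.015

HBEF  blind CzI 0.303   calibrated CzI 0.859
EB    blind CzI 0.269   calibrated CzI 0.773
WB    blind CzI 0.352   calibrated CzI 0.823
```

The six synthetic example species split the plot according to their
suitability under the generated drivers: the low fern and the
shade-tolerant herb dominate because their light optima sit near the dim
forest floor, while the light-demanding herb is excluded. The site rows
recompute community similarity between observed covers and the blind
(uncalibrated) versus calibrated model runs at the three packaged sites:
calibration raises the agreement from roughly a third of the total cover
correctly placed to over 80%.

A command-line interface mirrors the library:
`vegniche synth | simulate | calibrate | evaluate | demo` (see
`vegniche --help`).

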