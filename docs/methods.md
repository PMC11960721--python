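# Methods

## Model structure

`vegniche` simulates the relative surface cover of a fixed list of
understory species from monthly environmental drivers. The chain is:

1. **Niche responses** (`vegniche.niche`). Per species and driver axis
   (soil-solution pH, soil-solution N, soil moisture saturation, light),
   the response is `exp(-(driver - opt)^2 / var)`. `var` carries squared
   driver units, read literally from the response formula; a
   `var_is_sd` option reinterprets `var` as a standard-deviation-like
   width and squares it internally for users who parameterize that way.
   Temperature is a closed-interval {0,1} window, not a Gaussian: the
   window form is the minimal assumption when no tail shape is specified,
   and it composes with the product rule as a hard gate. Responses below
   1e-300 are clamped to exactly 0; at that magnitude the species is
   excluded regardless and the clamp avoids subnormal noise.

2. **Drivers** (`vegniche.drivers`). Monthly per-layer series (pH, N,
   moisture) plus a profile-wide soil temperature and forest-floor light
   fraction, validated on read (ranges, strict monthly grid). A species
   experiences the thickness-weighted mean of each driver over the soil
   layers its rooting depth intersects, a partially reached layer
   contributing its intersected thickness; the weighted mean is the least
   committal reading of "roots give access to different layers", and a
   `deepest`-layer mode is available as the obvious alternative. Rooting
   depths below the profile are clamped to the profile bottom with a
   warning.

3. **Community assembly** (`vegniche.community`). Light available to a
   plant is `floor_light * (1 - s * C_taller)` — linear occlusion by the
   summed cover of strictly taller plants with shading efficiency
   `s = 0.75` by default, clipped to `[floor_light*(1-s), floor_light]`.
   Equal shading heights do not shade each other (symmetric,
   order-independent tie rule). Competitive strength is suitability
   itself (shading already enters through the light response); an
   optional dominance exponent `gamma` (`strength = suitability**gamma`,
   default 1) sharpens dominance if needed. Covers are
   strength-proportional and normalized over the modeled species — no
   explicit bare-ground pool, matching relevé tables whose columns close
   to ~1. Within a year, growing-season (default May–September) monthly
   suitabilities are averaged into strengths and the cover/shading
   interdependence is solved by damped fixed-point iteration (damping
   0.5, tolerance 1e-6 on the max cover change, cap 100 iterations;
   non-convergence returns the last iterate flagged). Years are chained
   with an inertia factor `lambda` in (0,1] (default 1 = instantaneous
   replacement); annual stepping reflects that the model targets
   year-scale, not sub-annual, community dynamics.

   Degenerate inputs: if every strength is zero the state is returned
   all-zero and flagged non-viable instead of raising on the 0/0
   normalization.

4. **Calibration** (`vegniche.calibration`). Niche parameters are
   expressed as integer class ranks through a class key (rank →
   physical optimum/tolerance); the default key spans pH 3–7, N 0–10
   mg/L, moisture 0.05–0.95 and light 0.02–1.0 in nine evenly spaced
   classes, with per-class tolerance equal to the squared class spacing
   (response e⁻¹ at the neighbouring class centre). The key is an
   explicit, replaceable YAML: site-specific keys should be supplied
   where they exist.

   Cover errors are classified qualitatively: *false dominant* (observed
   < 10%, simulated > 20%), *suppressed dominant* (observed ≥ 20%,
   underestimated by > 5 points), *sub-dominant error* (observed in
   [10%, 20%], error > 5 points), a residual *other* class for remaining
   > 5-point errors (the three named patterns do not tile the plane), and
   *ok* (within 5 points). "5% error" is read as 5 absolute percentage
   points of cover; relative error is undefined at observed 0. The axis
   blamed for an error is the one with the smallest response factor for
   an underestimated species, or the largest exceedance over the
   community-mean response for an overestimated one; ties break in the
   fixed order light, N, pH, moisture.

   The calibration loop takes one single-class move at a time and
   re-simulates after every move. Candidate moves for a species are
   grouped by preference — identified-axis optimum (error-reducing
   direction first), identified-axis tolerance (×1.5 or ÷1.5), other
   axes' optima, other axes' tolerances, shading-height class — and a
   later group is considered only when no earlier-group move is
   admissible, keeping edits close to the diagnosed axis and trying
   optima before tolerances. A move is admissible when it strictly
   reduces the species' own |error| and strictly reduces the community
   total Σ|P−O| (strictness guarantees termination), and preferentially
   when it leaves every currently-fitted species within 5 points. Among
   offenders — visited false dominants first, then suppressed dominants,
   then sub-dominants, then residual errors, worst error first — the move
   with the largest total-error reduction is accepted. Experience with
   seeded recovery experiments shaped two departures from a strictly
   sequential per-category procedure: first, because covers are
   normalized, a large corrective move necessarily redistributes cover
   and can push a marginally-fitted species just past 5 points, so when
   no move respects that veto one boundary crossing is allowed (the
   pushed species rejoins the queue and is repaired next); second,
   category-by-category processing tended to "fix" species whose
   inflation was merely collateral of a collapsed dominant, so the
   total-error criterion arbitrates across categories. After every
   species is within 5 points (or stuck), a **polish phase** continues
   with the same move machinery, worst-error species first, accepting
   only moves that reduce the total error by at least 1e-3 without
   pushing any species out of tolerance. Polish is what turns
   "all within 5 points" into near-exact recovery when an exact solution
   exists; its minimum-gain rule makes calibration idempotent (a second
   run performs zero moves). Constraint windows (default ±2 classes
   around the starting rank, standing in for literature bounds) are never
   crossed; species whose windows are exhausted are reported unresolved,
   not raised. The report records net revisions per species and axis —
   a move later undone cancels its record.

5. **Metrics** (`vegniche.metrics`). NAE `(P̄-Ō)/Ō`; NRMSE
   `sqrt(Σ(Pᵢ-Oᵢ)²/N)/Ō`; zero-intercept slope `ΣPO/ΣO²` of predicted on
   observed with through-origin standard error
   `sqrt(Σr²/(N-1)/ΣO²)` and Pearson correlation (paired with a linear
   1:1 slope, a rank correlation would be inconsistent); Czekanowski
   similarity `1 - Σ|P-O|/Σ(P+O)` over the union of species, absences
   counted as zero cover. Monthly model output is paired with dated
   observations by yearly medians (an `agg="mean"` switch exists);
   observation years outside the modeled span are dropped with a log
   message. Metrics raise a typed error where undefined (observed mean
   zero, all-zero cover vectors) rather than returning NaN.

## Synthetic driver generator

The generator (`generate_synthetic_drivers`) emulates monthly
biogeochemical-simulator output for an acid northeastern hardwood soil:
per driver, `baseline + amplitude*sin(2π·month/12 + phase) +
trend_per_decade*elapsed_decades + noise`, clipped to physical ranges.
Defaults: pH 4.3 (amplitude 0.05, slow +0.05/decade recovery, σ 0.04),
N 1.2 mg/L (amplitude 0.4, −0.15/decade declining deposition, lognormal
σ 0.15 — multiplicative noise keeps concentrations non-negative and
right-skewed like observed solution chemistry), moisture 0.55 (amplitude
0.12, summer drawdown via phase, σ 0.04), soil temperature 6 °C
(amplitude 9, σ 0.8), floor light 0.12 (amplitude 0.04 peaking before
leaf-out, σ 0.015). Layer drivers add a fixed down-profile gradient
(pH +0.5 surface→bottom, N −0.4, moisture +0.15). All randomness flows
from one integer seed; identical configurations are bit-identical.

What the generator does *not* emulate: autocorrelated weather,
deposition-history structure, snowmelt events, inter-layer hydrological
coupling, or measurement error in relevés. Tests passing on synthetic
drivers therefore demonstrate the internal consistency of the community
model and the recoverability of niche parameters under controlled
perturbation — not predictive skill on field data, which requires a real
biogeochemical driver series and real relevés.

## Packaged site data

Three CSVs carry the published observed/blind/calibrated relative cover
tables for the HBEF, EB and WB hardwood sites (45 species across sites;
19 with reported observed values at HBEF, 33 each at EB and WB), printed
at two-decimal precision. One species row duplicated in the source table
is collapsed on load. The printed EB calibrated column sums to 0.82
rather than ~1; the data are kept as printed, and this deficit is the
likely reason recomputed EB similarity values sit up to ~0.06 from the
originally reported ones, while HBEF and WB recompute to within ~0.01.

## Numerical choices and problem sizes

Fixed-point damping 0.5 with tolerance 1e-6 converges in well under 100
iterations on all tested random communities. The seeded recovery
experiments used in the test suite run 8 species over 3 years of
synthetic drivers with 3 displaced optima (2 classes each, on the
largest-cover species, shifted away from the prevailing driver value) —
sizes chosen so a full 20-experiment batch exercises hundreds of
re-simulations while each individual simulation remains a
fraction-of-a-second computation. Root-zone aggregation is memoized per
(month, depth, profile) on the driver series, which repeated
re-simulation during calibration relies on.

## Known limitations

- The strength-to-cover rule (proportional normalization) and the linear
  shading occlusion are declared substitutes for the original model's
  unpublished functional forms, chosen as the simplest rules consistent
  with normalized covers and "taller shades shorter".
- Calibration is greedy and single-move; it finds *a* table within
  tolerance, not a unique or globally optimal one. Niche parameters
  recovered from cover data are only identifiable up to compensating
  changes (e.g. tolerance vs optimum trades).
- No colonization from outside the species list, no dispersal, no
  spatial structure, no phenology or biomass of the understory plants —
  cover fractions only.
- The temperature window has hard edges; any smoothing the original
  formulation may apply at the boundaries is not represented.
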