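# Methods

This note records the scientific choices behind `sprucestand`: the model
equations, the parameter defaults and their rationale, what the synthetic
generators do and do not emulate, and the numerical conventions.

## Allometry

Height and mass follow the even-aged uniform height curve and a stem
dry-mass power law with a 0.5 carbon fraction:

    h(dbh) = h_offset + exp(a − dbh_scale/dbh),   a = ln(h_max − h_offset)
    m(dbh) = 0.5 × 0.286 × (dbh·h)^1.138

Defaults: `h_max = 25 m`, `h_offset = 1.3 m` (breast height),
`dbh_scale = 7.55 cm`.  The intercept is *derived* from `h_max` rather
than stored as a rounded decimal: with `a = ln(23.7) ≈ 3.16547` the 7 cm
survey minimum maps to 16.69 kgC, whereas the rounded `a = 3.17` would
give 16.76 kgC.  Storing the asymptote keeps the truncation mass
reproducible to the printed hundredth.

The inverse `dbh_from_mass` is a bracketed Brent root-find on
[0.1, 500] cm at 1e−8 relative tolerance; monotonicity of the forward map
guarantees uniqueness.  Stand-level unit conversions (kgC m⁻² ↔ tC ha⁻¹,
factor 10) are centralised here.

## Mass-class demography

The stand is a number density over K geometric mass classes
(`m_i = m_seed·ratio^i`; defaults K = 10, `m_seed` = 1 kgC, ratio = 2),
with class edges at geometric midpoints.  Per-class height and dbh come
from the allometry; crown area and leaf carbon scale as `m^(2/3)`:

* `crown_area = 0.27 · m^(2/3)` m² — calibrated once so that a mature
  stand (~1300 trees ha⁻¹ at ~150 kgC mean mass) just closes its canopy;
* `leaf_carbon = 0.177 · m^(2/3)` kgC with SLA 8 m² kgC⁻¹ — calibrated so
  the same mature stand carries LAI ≈ 5.5.

One demographic step (dt = 1/12 yr) applies, in order:

1. **Growth.**  The growth share `(1−α)·max(NPP,0)·dt` is distributed over
   trees ∝ `m^φ·(1−ν_above)`, where `ν_above(i)` is the crown cover of
   strictly larger classes (larger trees shade smaller, never themselves).
   The per-tree growth becomes an upwind number flux
   `n_i g_i/(m_{i+1}−m_i)` between adjacent classes, which conserves
   carbon identically under the ladder's bookkeeping.  The top class is
   absorbing: its growth accumulates in an explicit mass-excess pool so
   neither trees nor carbon leak off the grid.
2. **Mortality.**  `n_i ← n_i·exp(−γ·dt)` with γ = 0.01 yr⁻¹ applied as an
   instantaneous rate (so a growth-free run recovers γ exactly from
   `−ln(N(t)/N(0))/t`); dead carbon joins the litter accumulator.
3. **Recruitment.**  `α·max(NPP,0)·(1−ν_total)·dt/m_seed` seedlings enter
   the lowest class; the reproduction carbon that finds no open ground
   goes to litter, so allocated NPP is fully accounted.  Defaults
   α = 0.05 (a low reproduction rate, as appropriate for a managed
   plantation), φ = 0.75.

Negative NPP (cold, dark months) is drawn from the litter accumulator and
never from live structure, which keeps the demography well-posed without a
starvation-mortality mechanism the model does not claim to represent.
Carbon closure (`Δbiomass + Δlitter = NPP·dt`) and exact tree-number
closure are regression-tested each step.

## Management

A single thinning removes fraction 1/3 of trees uniformly from every class
at the first step where stand age ≥ 25 yr (an internal flag prevents
refiring).  Removed carbon splits by the PFT partition — wood 0.80 to a
product pool, leaf 0.05 + root 0.15 to litter.  The split fractions are a
package choice (the destination of each part is fixed; the partition
itself is typical for mature conifer stems).  The product pool is
non-decaying by design, with the decay constant exposed in the event/pool
bookkeeping as an obvious extension point; uniform removal leaves the
normalised size distribution, and hence the biomass Gini, unchanged at the
event instant — a property the tests exploit.

## Productivity (declared stand-in)

The productivity module is deliberately parsimonious — a light-use
efficiency model, not a full photosynthesis/energy-balance scheme — so
that the CO₂ and weather pathways stay exercisable at desk scale:

    GPP = LUE_max · f_T · f_VPD · f_CO2 · APAR
    APAR = SW↓ · 0.5 · (1 − exp(−0.5·LAI))
    f_T = exp(−((T−T_opt)/T_width)²),  f_VPD = 1/(1+VPD/VPD_half)
    f_CO2 = [(ca−Γ)/(ca+2Γ)] / [(ca_ref−Γ)/(ca_ref+2Γ)]
    NPP = (1−g_frac)·(GPP − R_ref·B·Q10^((T−10)/10))

Defaults: LUE_max = 0.0020 kgC MJ⁻¹ APAR (≈2 gC per MJ absorbed PAR, a
typical conifer value), T_opt = 16 °C, T_width = 11 °C, VPD_half = 12 hPa,
Γ = 40 ppm, ca_ref = 330 ppm (early-1970s atmosphere, so the fixed-CO₂
control has factor 1), R_ref = 0.055 yr⁻¹ per unit biomass at 10 °C,
Q10 = 2, growth-respiration fraction 0.25.  LUE_max and R_ref were
calibrated once against the default synthetic driver so a 45-year thinned
transient run reaches a mature-stand biomass of ~245 tC ha⁻¹ (within the
150–280 tC ha⁻¹ magnitude bracket of intensively managed high-yield-class
spruce) with mature GPP near 2 kgC m⁻² yr⁻¹, then frozen.  The CO₂ factor
is strictly increasing and saturating, which makes the
transient-vs-fixed-CO₂ biomass ordering a testable monotone property.

Coupling: productivity is evaluated on daily driver rows (VPD from the
August–Roche–Magnus saturation pressure and relative humidity), summed
over each calendar month with LAI held at its start-of-month value, and
handed to one demographic step of 1/12 yr.

## Flux inference

The observation-side chain mirrors standard practice at instrumented
sites:

1. soil respiration at the tower timestep by a Q10 function anchored at
   the nearest-in-time chamber visit (ties to the earlier point),
   `R(t) = R_obs·Q10^((T(t)−T_obs)/10)` — exact at chamber timestamps;
2. a root share of soil respiration of 0.42 (range 0.30–0.50);
3. tree respiration `R_tree = R_eco − (1−f_root)·R_soil` (roots belong to
   the trees);
4. `NPP = GPP − R_tree`, with the uncertainty band inverted (more root
   respiration ⇒ more tree respiration ⇒ less NPP).

The soil Q10 defaults to 2.0 and is a prominent, configurable assumption.
The Magnus constants are the common published variant
(6.1094 hPa, 17.625, 243.04 °C).  Fluxes are stored as kgC m⁻² per step; a
tested converter accepts µmol CO₂ m⁻² s⁻¹ (×12.011e−9×Δt s).  Radiation
clean-up truncates shortwave at zero and replaces longwave wholly by a
trusted substitute series, extended beyond its coverage by its day-of-year
mean cycle (the leap day falls back to day 365).

## Evaluation statistics

* **Survey processing**: each tree in `n_plots` plots of `plot_area` m²
  represents `10000/(n_plots·plot_area)` trees ha⁻¹; dbh below the survey
  minimum is dropped with a warning.
* **KDE fit**: Gaussian KDE in *log mass* (the classes are geometric) with
  Scott's-rule bandwidth, integrated over class edges and renormalised so
  total density is conserved exactly; degenerate samples fall back to
  direct binning.
* **Gini**: Lorenz-curve (trapezoid) form on trees ranked by mass, with a
  weighted variant for class-resolved stands; equals the O(n²)
  mean-absolute-difference definition to 1e−12 (property-tested).
* **χ²**: classes with centre mass below the truncation mass are dropped;
  both distributions are scaled to the observed tree count; zero-expected
  cells are pooled into their upper neighbour; dof = cells − 1.  With the
  default 10-class ladder, 5 cells sit above the 16.69 kgC truncation, so
  dof = 4; the actual cell count is always reported.
* **KS**: sup distance between the weighted empirical mass CDF and the
  class-step CDF, evaluated at both one-sided limits of every step point;
  p-values from the asymptotic KS distribution with the observed tree
  count as effective n (p < 1e−6 prints as ~0 in practice).
* **Flux statistics**: RMSE and squared Pearson correlation on the joint
  non-missing overlap, optionally aggregated to calendar months;
  zero-variance series leave R² undefined rather than 0 or 1.
* **Seasonal–diurnal matrices**: month × half-hour cell means (12×48),
  with cellwise differences for paired series.

## Synthetic generators

The generators emulate the *statistical structure* of the study site, not
its actual weather:

* **Weather** — temperature as seasonal sinusoid (amplitude 5.5 °C,
  peaking late July) plus AR(1) anomalies (ρ = 0.8, σ = 2.5 °C) around a
  7.8 °C mean; precipitation as a two-state Markov occurrence chain
  (stationary wet probability 0.5625, wet-after-wet 0.65) with gamma
  amounts whose scale is derived so the expected annual total is exactly
  1352 mm; shortwave from solar geometry at 55.2° N times an
  Angström-type cloud transmission, with a diurnal solar-zenith cycle at
  half-hourly cadence (zero at night); longwave via Stefan–Boltzmann with
  cloud-dependent emissivity; bounded-noise humidity, pressure and wind.
* **CO₂** — constant (fixed-control) or linear ramp; the default
  1.756 ppm yr⁻¹ from 330 ppm reproduces the ~79 ppm 1973→2018 rise.
* **Survey** — Poisson per-plot counts at a target density with lognormal
  integer dbh (defaults μ = ln 23, σ = 0.22, chosen once so a mature
  synthetic stand has ~1350 trees ha⁻¹ and mean height 17–18 m);
  sub-minimum draws are resampled so density and unimodality survive
  truncation.
* **Fluxes** — GPP from the package's own LUE model at fixed LAI, soil and
  above-ground respiration as exact Q10 responses, Reco and NEE assembled
  self-consistently, chamber visits as exact subsamples, and missing-data
  gaps injected into the met columns.  Because the truth is generated
  with the same constants the inference assumes, the inversion is exact —
  which is precisely what makes it a parameter-recovery test.
* **WCC table** — logistic stand-growth increments per five-year period
  with repeated light removals in the thinned variant, in tCO₂ ha⁻¹, as a
  synthetic stand-in for the real lookup table (not redistributed here).

What the generators do **not** emulate: real interannual weather anomalies
(droughts), spatial structure, observation error in the fluxes, size-biased
thinning, or disturbance mortality.  Passing tests therefore demonstrate
internal consistency, directional responses (thinning, CO₂) and magnitude
plausibility — not skill against the real site's historical record, which
requires the real drivers and a full physiological model.

## Numerical conventions and degenerate inputs

Time step 1/12 yr for demography (densities stay non-negative under
defaults up to dt = 0.1 yr, regression-tested); bisection bracket
[0.1, 500] cm for the allometric inverse; KDE renormalisation conserves
density to 1e−12; carbon closure asserted at 1e−8 relative per step;
empty stands yield zero aggregates; a truncation mass above the top class
zeroes structure statistics but not LAI (a whole-stand quantity); repeated
thinning raises an error rather than silently refiring.

## Problem sizes

The shipped tests and the acceptance script use 30–45-year simulations at
daily driver cadence with monthly demographic steps, single synthetic
years at half-hourly cadence for flux work, and 30 generated years for
climatology checks — sizes chosen so the whole suite runs in seconds while
every mechanism (canopy closure, the thinning event, CO₂ divergence, the
full inference chain) is exercised end to end.

## Known limitations

Single PFT and single stand; no soil-moisture, energy-balance or nitrogen
feedbacks (the productivity stand-in is a declared simplification); no
size-dependent mortality or windthrow/drought disturbance, so simulated
mature stands keep more small trees and a wider size spread (higher Gini)
than a real surveyed plantation; the product pool does not decay; thinning
is a single uniform event, not a repeated selective regime.
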