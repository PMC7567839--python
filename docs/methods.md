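# Methods

## Overview

The package implements a two-part analysis of multi-decade bottom-trawl
survey data: (i) quantify each species' association with four
environmental covariates — bottom temperature (°C), bottom salinity
(psu), depth (m), sediment grain size (mm) — as the deviance explained
by single-covariate negative-binomial GAM smooths; (ii) quantify each
species' historical distribution change between an early and a late
5-year window as centroid displacement, 95% kernel-density range-area
change, and range-edge movement; then relate (i) to (ii) across species
with nonparametric rank-sum tests. A synthetic survey generator with
known truth replaces restricted survey data so the whole chain is
testable.

Seasons are analyzed independently end to end: every fit, metric, and
comparison is computed per (species, season).

## Predictor-importance model

For one species, season, and covariate x, CPUE y is modeled as

    y ~ NB(mu, theta),  log mu = beta0 + f(x),

with f a cubic B-spline smooth (basis dimension k = 10) under a
quadratic difference penalty. CPUE is treated as a raw nonnegative
quantity; the NB log-likelihood is written with gamma functions, so
non-integer (calibrated) CPUE is acceptable as a quasi-likelihood.
Importance is

    dev_expl = (D_null − D_model) / D_null,  clipped to [0, 1],

where both deviances use the package's own NB deviance

    D = 2 Σ [ y log(y/mu) − (y + theta) log((y + theta)/(mu + theta)) ],

evaluated at the model's profiled theta (y log(y/mu) := 0 at y = 0).
The null model is the intercept-only NB fit, whose mean MLE is the
sample mean for any theta. The strongest predictor is the argmax of
dev_expl over the four covariates, with exact ties resolved by the
fixed order (btemp, bsalin, depth, grainsize) and logged.

Numerical choices:

* Backend: statsmodels `GLMGam` (penalized IRLS). Its reported deviance
  is cross-checked against the package's own formula to 1e-6 relative
  on every fit; disagreement marks the cell non-convergent.
* Smoothing parameter: selected by GCV, n·D/(n − edf)², over a 9-point
  log-spaced grid (1e-2 … 1e6) with edf = trace of the hat matrix. REML with an outer Newton step is the field-standard
  criterion, but no REML selection for penalized GLMs is available in
  the installed stack, so the GCV grid is the documented fallback (recorded in each fit record
  as `lambda_method="gcv_grid"`).
* Dispersion theta: moment-initialised, then profiled — two rounds of
  (fit means at fixed theta) → (maximise the NB log-likelihood over
  log-theta at fixed means), followed by a final refit. Bounds
  [0.05, 1e5].
* Cells with < k + 5 complete rows, < 3 distinct covariate values, a
  constant response, or failed/inconsistent fits are reported as
  missing, never as 0 — a zero would bias the argmax toward the
  remaining covariates.

## Range metrics

Hauls of one species-season are restricted to each period (defaults
1986–1990 and 2014–2018) and weighted by CPUE.

* **Centroid**: arithmetic weighted mean of latitude and longitude (a
  guard rejects longitude spans ≥ 180°, far from the antimeridian the
  planar mean is adequate). **Shift** is the haversine great-circle
  distance between the two period centroids on a sphere of radius
  6371.0088 km (IUGG mean; an ellipsoidal distance would differ by
  < 0.5%).
* **Range**: a product-Gaussian weighted KDE on a regular lon/lat grid
  (default 200 × 200, padded by 3 bandwidths). Per-axis bandwidth is
  the weighted Scott rule h = sigma_w · n_eff^(−1/6) with effective
  sample size n_eff = (Σw)²/Σw². Kernel centers are shrunk toward the
  weighted mean by (1 + h²/sigma²)^(−1/2) per axis ("variance-matched"
  smoothing, as in the smoothed bootstrap): without it the smoothed
  density's variance exceeds the sample's by the factor (1 + h²/sigma²)
  and isopleth areas are systematically inflated by ~6% at n = 5000.
  With it the 95% isopleth area of a standard bivariate normal sample
  matches the analytic value pi·chi²₂(0.95) within ~2%. Disable via
  `KdeOptions(variance_matched=False)`.
* **Isopleth**: cells ranked by density (mass / area) in stable
  descending order and accumulated until cumulative mass first reaches
  the level; the stable sort makes exact-tie behaviour deterministic
  (a uniform 100-cell surface at level 0.95 selects 95 cells). Area is
  the sum of selected cell areas with a cos(latitude) correction
  (`planar=True` uses unit cell areas for analytic checks). Percentage
  range-size change is 100·(A₂ − A₁)/A₁ — unit-free, so the km² choice
  does not propagate.
* **Edges**: min/max cell-center latitude of the 95% region;
  d_north/d_south are period-2 minus period-1 values.

Areas are bandwidth-sensitive; bandwidth, grid size, level, and
variance matching are all exposed in `KdeOptions`. Metrics are
invariant to uniform rescaling of CPUE.

## Group comparisons

Two-sided Mann-Whitney/Wilcoxon rank-sum tests on each metric between
every unordered pair of groups. With n1 + n2 ≤ 12 and no ties the exact
null distribution is used; otherwise the normal approximation with
midranks, tie correction, and continuity correction — bit-reproducible
either way. Groups with < 3 members are flagged low-power. Holm
adjustment across the pairs of one family is available but off by
default; both adjusted and unadjusted p-values are emitted when on,
so either convention can be reported.

## Synthetic survey generator

What it emulates: a stratified random survey (stations allocated
proportionally to stratum area — round half-up, floor of one per
stratum — uniform within stratum rectangles), two seasonal passes per
year over 33 years, an in-situ covariate suite, and negative-binomial
catch noise (Var = mu + mu²/theta, default theta = 2).

Default domain and effort were chosen to match the surveyed shelf
system being emulated: ~285,000 km² (10° latitude × 3° longitude) at
1.3e-3 stations/km² ≈ 370 stations per seasonal pass, i.e. mean station
spacing under 20 km. This matters because the two-period centroid-shift
noise floor scales as sqrt(domain area / station count) regardless of
how concentrated a species is; at real-survey spacing the floor for a
non-shifting species is well under 10 km, whereas a desk-scale sparse
survey of the same domain cannot resolve shifts below ~15 km.

Fields: temperature = linear latitudinal gradient (1 °C per degree,
colder poleward) + static along-shelf anomaly + seasonal offset
(spring −0.5, fall +0.5 °C) + linear warming (default 0.04 °C/yr,
the rapid-warming regime of the emulated shelf); salinity = latitudinal
gradient + interannual basin-wide anomaly; depth = static offshore
gradient with a latitudinal ripple; grain size = static lognormal
patchy field (Gaussian-smoothed white noise, patch scale ~0.5°).

Species respond through Gaussian niche terms on the log-CPUE scale:
log mu = baseline + Σ_c w_c · exp(−((x_c − opt_c)/b_c)²/2). The default
community has 4 species per life-history group:

* **pelagic** — strong thermal niche (w = 5) plus weak depth
  preference, baseline −1.0, imposed shift 70 km/decade. The strong
  weight and low baseline keep the background (out-of-niche) biomass
  negligible; with a weak response the domain-wide background pulls the
  weighted centroid toward the domain center and the realized shift
  under-runs the imposed rate.
* **benthic** — grain-size niche only (static), hence anchored: the
  expected-CPUE surface is identical in every year and the true shift
  is exactly 0.
* **demersal** — temperature and grain size weighted equally, imposed
  shift 35 km/decade. Because half the niche is static, the *realized*
  centroid shift is attenuated to roughly 40% of the thermal-optimum
  drift; the truth table records the imposed optimum-path displacement,
  not the attenuated realized value, so only pelagic and benthic
  species are used for quantitative recovery checks.

Imposed shifts move the thermal optimum *value* at the rate
(warming − gradient · drift), which makes the latitude where the
deterministic temperature field equals the optimum drift poleward at
exactly the configured km/decade — 0 km/decade actively pins a
thermal species against the warming trend. The truth table stores the
per-year optimum-latitude path and the displacement between the two
period midpoints (2.8 decades apart: 70 km/decade → 196 km).

All randomness flows from one root seed through purpose-keyed child
streams (crc32-hashed keys), so identical configurations are
byte-identical regardless of call order.

What the generator does **not** emulate — and what a green recovery
test therefore does not establish: vessel/gear calibration, day-night
and tow-duration effects, species interactions, fishing pressure,
recruitment pulses, spatially correlated catch noise, irregular
stratum geometry, mid-series design changes. Environmental fields are
smooth and the niche model matches the fitted model family
(well-specified case); real-data deviance explained will generally be
lower and noisier.

## Inclusion filters

* Strata must have ≥ 1 haul in every (year, season) cell of the study
  window, else they are dropped entirely.
* Species are retained only if, in every season: present (CPUE > 0 in
  ≥ 1 haul) in at least floor(0.5 · n_years) distinct years — 16 of 33
  under defaults — and summed CPUE strictly > 20 within the first and
  last 5-year windows. "Strictly greater" is deliberate: a window sum
  of exactly 20 drops the species. The presence floor uses floor, not
  ceil, to reproduce the 16-of-33 reading of "at least half of 33
  years". The > 20 rule is read as a per-season sum over the window's
  hauls; per-survey and positive-haul-count readings are plausible
  alternatives, so the threshold and window length are configurable.
* The substrate join is great-circle nearest neighbour with a 50 km
  default cutoff and lower-index tie-break.

Filters are idempotent and monotone in their thresholds.

## Known limitations

* GCV smoothing selection can under-smooth relative to REML at small n;
  spurious deviance explained for an unrelated covariate is < 2% at
  n = 2000 but can reach ~5% at n = 500.
* KDE range areas depend on bandwidth; only the percentage change is
  scale-robust. The cos-latitude cell-area correction treats cells as
  planar rectangles (adequate at 0.05° cells).
* The centroid/edge machinery assumes the domain stays > 180° away
  from the antimeridian.
* Exact rank-sum p-values are only available for tie-free samples with
  n1 + n2 ≤ 12; elsewhere the corrected normal approximation is used
  (null rejection rate at alpha = 0.05 measured at 0.047 with
  n = 15 + 15).
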