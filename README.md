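# rangeshift

Tools for asking why some fish species shift their geographic
distributions under ocean warming while others stay put. The package
links **how strongly a species' abundance is tied to each environmental
variable** (bottom temperature, bottom salinity, depth, sediment grain
size) to **how far its distribution actually moved** over a multi-decade
bottom-trawl survey — the hypothesis being that species bound to static
seafloor properties (substrate, depth) shift less than species tracking
dynamic oceanography (temperature, salinity).

It is aimed at spatial ecologists and fisheries scientists who want the
full analysis chain as tested, reusable Python, together with a
synthetic survey generator with *known truth* so every stage can be
validated without access to restricted survey data.

## The analysis

Given a long-format survey table (haul, year, season, stratum, lat/lon,
environmental covariates, species, CPUE):

1. **Filtering** (`rangeshift.ingest`) — keep strata sampled every year
   in every season; keep species present in ≥ half the years per season
   (16 of 33 under defaults) with summed CPUE > 20 in both the first
   and last 5-year windows. A substrate grain-size layer can be joined
   by great-circle nearest neighbour.
2. **Predictor importance** (`rangeshift.importance`) — for each
   species × season × covariate, fit a single-covariate penalized-spline
   GAM with a negative-binomial family and log link (basis dimension
   k = 10) and record the deviance explained against the intercept-only
   null,

       dev_expl = (D_null − D_model) / D_null,
       D = 2 Σᵢ [ yᵢ log(yᵢ/μᵢ) − (yᵢ+θ) log((yᵢ+θ)/(μᵢ+θ)) ].

   The covariate with the largest deviance explained is the species'
   *strongest predictor*.
3. **Range metrics** (`rangeshift.rangemetrics`) — for two periods
   (1986–1990 vs 2014–2018 by default): CPUE-weighted mean centroids
   and the great-circle distance between them (`shift_km`, sphere
   R = 6371.0088 km); the 95% isopleth area of a CPUE-weighted Gaussian
   KDE (the species' range, km²) and its percentage change
   100·(A₂−A₁)/A₁; northern and southern range-edge latitudes of the
   95% region and their change.
4. **Group comparisons** (`rangeshift.compare`) — two-sided Wilcoxon
   rank-sum tests of each shift metric between strongest-predictor
   groups and between life-history groups (benthic / demersal /
   pelagic), exact for small tie-free samples, tie- and
   continuity-corrected otherwise; optional Holm adjustment.

`rangeshift.simulate` generates the stand-in data: stratified-random
stations allocated proportionally to stratum area, a warming temperature
field with a latitudinal gradient, static depth and patchy substrate,
Gaussian niche responses per species archetype, negative-binomial catch
noise, and a configurable imposed poleward drift whose true magnitude is
written to a truth table. `rangeshift.pipeline.run_all` chains all
stages and writes every table plus a checksummed reproducibility
manifest.

## Worked example

`examples/` holds one short script per capability. For instance,
predictor importance for a substrate-bound species
(`examples/03_predictor_importance.py`) prints

```
covariate  dev_expl  theta  n_obs  converged
    btemp    0.0560 1.0547  12210       True
   bsalin    0.0321 1.0234  12210       True
    depth    0.0110 0.9971  12210       True
grainsize    0.4288 1.9469  12210       True

strongest predictor: grainsize
```

— the generating niche used only grain size, and the single-covariate
GAMs recover exactly that (43% of deviance explained; the residual
temperature/salinity signal is spatial correlation). Range metrics for
a shifting pelagic vs an anchored benthic species
(`examples/04_range_metrics.py`):

```
  species  shift_km  pct_area_change  d_north  d_south
benthic_1      2.40            -2.34     0.05     0.24
pelagic_1    182.65             6.41     2.08     1.45
```

against imposed truths of 0 km and 196 km, and the group-level rank-sum
test (`examples/05_group_comparison.py`) separates the groups at
p = 0.0022 (the exact two-sided minimum for 6 vs 6 with complete
separation).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic scenario from the seed, runs the full
pipeline end-to-end (filters → GAM importance → range metrics →
comparisons), writes the stage tables under `scratch/acceptance_run/`
and the JSON report object to `--out` (~4 min on one CPU). The
scientific validation itself — analytic oracles for the NB deviance,
KDE isopleth area, geodesy and rank-sum exactness, plus truth-recovery
of imposed shifts and dominant predictors — lives in
`tests/test_acceptance.py`.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its deliberate simplifications, numerical choices, and
known limitations.
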