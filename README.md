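# ingrowth

Tree recruitment (in-growth) analysis from repeated forest-inventory tree
lists: a tested, reusable pipeline that derives stand-structure and climate
covariates, groups species by shade/drought tolerance, fits a hierarchical
negative-binomial recruitment model with an in-repo MCMC sampler, and turns
posterior draws into effect estimates, effect curves and interaction
surfaces. A synthetic-data module emulates the inventory structure so the
whole pipeline can be exercised without restricted inventory data.

## Pipeline

| Module | What it does |
| --- | --- |
| `ingrowth.covariates` | Seasonal degree-day sum (base 5.5 °C, April–October), slope/aspect-corrected Thornthwaite water balance, soil bucket size |
| `ingrowth.inventory` | Recruitment counts (first exceedance of the DBH calipering threshold), basal area / stem density / plot shade-casting ability, DBH-threshold harmonization |
| `ingrowth.traits` | Trait scaling (mean 0, sd 2), six-centroid Lloyd k-means in (drought, shade) space, `D#S#` labels, genus fallback |
| `ingrowth.model` | Standardized design with offsets and two interactions, VIF screen, NB2 likelihood (plus Poisson / zero-inflated / hurdle variants), adaptive HMC or MAP+Laplace fitting, split rank-normalized R-hat & ESS, scaled quantile residuals, family comparison |
| `ingrowth.effects` | Mean-over-groups + deviation effect summaries with 95% credible intervals, per-variable effect curves over the 1st–99th percentile, basal-area × stem-density surfaces at the 10/30/50/70/90th density percentiles |
| `ingrowth.synthdata` | Correlated covariates on realistic scales, synthetic species pools and tree lists, counts from the generative model with known parameters, a parameter-recovery harness |

## Model

Counts of recruits per plot × period × species follow an NB2 distribution
with mean

```
log mu = log(area × period) + beta0[g] + u0_plot[i] + u0_species[j]
         + sum_m (beta[g, m] + u_species[j, m]) * x[, m]
```

where `g` indexes trait groups, the six standardized main effects are basal
area, stem density, shade-casting ability, degree-day sum, water balance and
bucket size, and the two interaction columns are `basal_area:stem_density`
and `wb:bs`. All random effects are normal; priors are weakly informative
(normal(0, 5) coefficients, half-normal(0, 2) scales, gamma(2, 0.1)
dispersion) and configurable.

The default sampler is an in-repo Hamiltonian Monte Carlo with dual-averaged
step size and diagonal mass adaptation, run on a non-centered, unconstrained
parameterization with analytic gradients; it is deterministic under a seed.
A `map_laplace` mode (L-BFGS mode + Gaussian approximation) is available for
fast replicate experiments; note that it intentionally trades calibration
accuracy for speed on hierarchical scale parameters.

PET uses the standard Thornthwaite (1948) monthly formula: heat index
`I = Σ (T_i/5)^1.514` over months with positive mean temperature, cubic
exponent `a`, and a daylength/day-count correction from latitude, multiplied
by the slope/aspect factor `kPMod ∈ [0.874, 1.25]` (continuous
`-cos(aspect)` interpolation by default, binary north/south as an option).

## CLI

```bash
ingrowth synth --out data/ --n-plots 200 --n-species 10 --seed 1
ingrowth covariates --climate climate.csv --terrain terrain.csv --out site_env.csv
ingrowth inventory --trees data/trees.csv --plots data/plots.csv \
    --traits data/traits.csv --threshold 7 \
    --out-observations obs.csv --out-stand stand.csv
ingrowth traits --traits data/traits.csv --out groups.csv
ingrowth fit --data data/ --out fit/ --chains 4 --iterations 3000 --warmup 1000
ingrowth effects --data data/ --out effects/
```

`fit` writes `draws.csv` (one row per chain × iteration) and
`diagnostics.json` (R-hat, ESS, VIF, residual summary); `effects` writes
`effects.csv`, `curves.csv` and `surfaces.csv`.

## Data formats

All interfaces are plain CSV: `climate.csv` (plot_id, date, tmean_c,
precip_mm), `terrain.csv` (plot_id, slope_deg, aspect_deg, sdr_m, awc_frac,
cfv_frac), `trees.csv` (plot_id, census_id, census_date, tree_id, species,
dbh_cm), `plots.csv` (plot_id, plot_area_ha), `traits.csv` (species, genus,
shade_tol, drought_tol, sca), plus the derived `observations.csv`,
`stand.csv`, `site_env.csv` and `groups.csv`.
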