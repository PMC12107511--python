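# Methods

`beeland` implements, end to end and on a synthetic study system, an analysis
of bumble bee occurrence probability under interacting pressures: local
land-use type, landscape natural-habitat availability, the duration of
substantial human modification of the landscape, cumulative pesticide
toxicity, a species' position within its realised thermal niche, and the
shift of that position caused by recent warming. This note records the
model, the constructions, the synthetic world the pipeline runs on, and the
choices made where the design was genuinely open.

## The occurrence model

Each row of the model table is a species × site pair within a study. The
response is presence/absence, fitted with a hierarchical logistic model

```
y_i ~ Bernoulli(p_i)
logit(p_i) = x_i' β + u_study[i] + u_site[i] + u_species[i]
```

with random intercepts for study (sampling protocol and broad geography),
site nested within study, and species. The fixed-effect design has 15
columns: intercept; a human-land-use indicator (natural = reference); six
continuous terms — natural habitat, ln(toxic load + 1), modification
duration, baseline thermal-niche position with a raw-coded quadratic, and
the niche-position shift — plus ln(elevation + 2) as a control, and the six
products of the land-use indicator with the pressure/niche columns.
Continuous covariates are centred and scaled (sample mean/SD over the fitted
rows); the scalers are stored in a JSON sidecar because the counterfactual
must re-express edited raw covariates on the fitted scale.

Raw quadratic coding was chosen over an orthogonalised basis: the fitted
curve is identical and scenario editing stays a column substitution. The
price is that the individual linear/quadratic coefficients are not
comparable one-to-one with an orthogonally-coded fit of the same data.

### Priors and sampler

Priors are weakly informative: Normal(0, 5) on standardised slopes, a
Student-t(3, 0, 2.5) intercept, half-t(3, 0, 2.5) random-effect standard
deviations. All three families admit conditionally conjugate scale-mixture
forms (inverse-gamma mixing for the Student-t; the Huang–Wand auxiliary
inverse-gamma pair for the half-t), so the model is fitted by an exact
Pólya-Gamma-augmented Gibbs sampler (Polson, Scott & Windle 2013): PG(1, η)
latent weights per row, a joint Gaussian draw of all fixed and random
effects from the sparse-structured normal equations, and inverse-gamma
updates of the variance components. PG variates are drawn from the
exponential-series representation truncated at 64 terms with the closed-form
tail mean added back; the neglected tail randomness is below 0.2 % of the
draw's mean, orders of magnitude inside Monte-Carlo error. The sampler is
validated in the tests against the analytic PG moments, against
logit(prevalence) for intercept-only data and against the statsmodels Logit
MLE in the σ → 0 regime.

Four chains with over-dispersed starts run 1000 warmup + 1000 retained
iterations each (4000 draws). Convergence is summarised by split-Rhat
(ArviZ) with a 1.01 flag threshold; a fit never fails silently — the
returned object carries a `converged` flag and the full Rhat table. The
variance components of the site term (600 levels, weakly identified) mix
most slowly and occasionally flag Rhat ≈ 1.05–1.1 at the default run length;
the fixed effects, which all downstream conclusions use, converge well below
the threshold.

### Diagnostics

*Bayes R²* uses the residual-variance form for a Bernoulli response: per
draw, `Var(μ) / (Var(μ) + mean(μ(1−μ)))`, with μ from fixed effects only
(marginal) or including the random intercepts (conditional).

*Moran's I* runs on site-level mean response residuals (observed minus
posterior-mean fitted probability, averaged over the species at a site),
once across all sites and once per study on that study's sites only.
Weights are row-standardised inverse distance among unique sites
(k-nearest-neighbour available as an option; no scheme is canonical for
this test and the choice is disclosed wherever results are reported).
Significance comes from a two-sided permutation test: 999 permutations of
the residuals over the fixed locations, doubling the smaller one-sided rank
with the +1 inclusion of the observed value. Under a spatially null model
this test rejects at the nominal 5 % rate (checked over 400 simulated
studies), so the per-study fraction of significant tests can be read
directly against the 5 % chance expectation.

## Covariate constructions

- **Landscape natural habitat** — a fractional natural-cover raster is
  bilinearly resampled to a 1-km equal-area grid, block-averaged by factors
  2 or 5 (missing cells excluded from block means), and each site takes the
  value of its containing cell without interpolation. Cells are registered
  half-open, `[edge, edge + grain)`; a site on a shared edge belongs to the
  higher-index cell. Rasters are serialised as ESRI ASCII grids — a plain
  text raster format — with km-based equal-area georeferencing.
- **Modification duration** — per coarse (0.5°-analogue) cell, the years at
  the 2005 reference epoch since the human-modified fraction (croplands +
  pastures + urban) first reached a threshold (default 30 %, with 10 % and
  50 % as sensitivity settings). Series never reaching the threshold get a
  duration of 0 years. The reference year is fixed at 2005, the epoch of
  the land-use reconstruction's end, since no per-site sampling year exists.
- **Pesticide toxic load** — Σ over crop groups and active ingredients of
  application density (kg/ha) divided by honey-bee contact LD50 (µg/bee);
  ingredients without an LD50 are excluded and counted (the synthetic
  ingredient list carries ~10 % missing LD50s to exercise this path). Low
  and high application estimates are both generated; low is the headline.
- **Thermal niche position** — realised niche limits per species are the
  means of the 5 lowest pooled monthly minima and 5 highest pooled monthly
  maxima over the 1901–1975 baseline at the species' record cells. Records
  are deduplicated to unique climate cells first, so record density does not
  weight the extremes; with fewer than five pooled values the mean of all
  available values is used, with a warning. Positions rescale local monthly
  maxima by the limits (0 = lower, 1 = upper), average the 12 months within
  a year, then average years within the period (baseline 1901–1975, recent
  2000–2014). Positions outside [0, 1] are genuine exceedances of the
  realised limits and are never clamped. The pooled-multiset reading of the
  extremes (rather than per-cell extremes) is one of two defensible
  readings; it is the one implemented throughout.
- **Absence inference** — within each study, species recorded at at least
  one site are treated as absent at the study's other sites; species never
  recorded in a study contribute no rows to it. Local land-use classes
  collapse to natural (primary + secondary vegetation) vs human-modified.

## The synthetic world

The generator produces, from one seed, a 400 × 400 km equal-area landscape:
a smooth fractional natural-cover field (source grain 1.25 km, so the 1-km
resampling step is a real interpolation), elevation, an 8 × 8 grid of
coarse cells carrying a 1500–2005 land-use history (logistic human
conversion with random onset, rate and ceiling, so threshold crossings span
the full duration range and some cells never cross), a 1901–2015 monthly
min/max temperature series with seasonal cycle, latitudinal gradient and a
post-1960 warming ramp (~1.3 °C by 2015), and per-crop × ingredient
application surfaces on a 10-km grid tied to end-state cropland cover.

The survey places 40 studies of 15 sites (clustered, SD 10 km) and a pool
of 8 species whose drawn niche limits put baseline positions across
~0.1–0.9, covering the quadratic's support. Local land-use class is drawn
with probability weakly coupled to surrounding natural habitat (coupling
0.45), which puts the class/habitat ANOVA R² near 0.05–0.08 — the weak
association regime in which local class and landscape habitat carry
distinct information. Studies target 6–8 of the pool's species; outcomes
are simulated from the model above with known coefficients (all pressures
harmful in natural habitat, interactions placing weaker pesticide and
climate-shift effects in human-modified sites) and σ_study = 0.8,
σ_site = 0.5, σ_species = 0.6. After absence inference ~3800–4100 rows
remain (species never "recorded" within a study drop out, exactly as the
inference rule dictates); a full 4-chain fit takes ~1–2 minutes on one CPU.
These sizes were chosen so the whole chain — including parameter-recovery
runs — executes comfortably on a single core.

What the generator does *not* emulate, and what passing tests therefore do
not show: real geography and projection handling (the world is born
equal-area; the Behrmann step reduces to bilinear resampling), hard climate
filtering of species ranges (simulated species can occur anywhere, so niche
limits re-estimated from simulated records reflect landscape climate
extremes rather than the generator's drawn limits — script 03 reports this
divergence explicitly), sampling-effort variation beyond the study
intercept, detection error, and temporal autocorrelation. Parameter
recovery here validates the estimator given the model, not the model given
nature.

### Simulation-based validation design

Recovery experiments simulate outcomes from the same covariate table that
is subsequently fitted (generator-drawn niche limits, shared scalers): the
standard simulation-based-calibration layout, in which coefficient coverage
is interpretable. Re-estimating niche limits from records is validated
separately (exact sort-oracle tests; the divergence report above) because
its estimation noise would confound coverage checks.

## The counterfactual

The reference condition sets natural habitat to 1, modification duration to
0, toxic load to 0 (so ln(x+1) = 0) and the niche-position shift to 0,
keeping baseline position, elevation, the estimated random intercepts and —
by default — the observed local land-use class (reductions are reported
*within* sampled natural and human-modified habitats, which requires the
class to persist; a flag resets it too, and script 05 prints both modes).
For each of 1000 posterior draws sampled without replacement,
`100 × (mean_ref − mean_actual) / mean_ref` is computed over each class's
species × site rows; positive values mean the pressures have reduced
occurrence. Summaries are the median and central 67 % / 95 % intervals of
the draw-wise values.

## Numerical conventions and edge cases

- Degenerate inputs raise typed errors: empty histories, thresholds outside
  (0,1), non-positive LD50s, elevations ≤ −2 m, degenerate niches
  (max ≤ min), constant natural habitat in the ANOVA, zero residual
  variance or coincident coordinates in Moran tests, unseen random-effect
  levels at prediction.
- A rank-deficient design errors at fit time and names suspect columns;
  scenario matrices (constant by construction) skip that check.
- All randomness flows from one integer seed through `SeedSequence`
  children (kept below 2³¹); identical seeds give bit-identical worlds,
  surveys, outcomes and draws.
- Block aggregation conserves the grand mean over complete blocks; toxic
  load is additive over ingredient partitions; niche position is affine
  equivariant (adding k °C to all monthly maxima adds k/breadth). These
  invariants are enforced by property tests.

## Known limitations

- The site-level variance component mixes slowly at the default run length;
  trust the flag, and lengthen warmup if σ_site itself is of interest.
- Moran's tests use one of several defensible weight schemes; fractions of
  significant studies can shift by a few points under k-NN weights.
- The abundance-based robustness model (zero-inflated negative binomial) is
  out of scope, as are IUCN risk screening, random slopes by species and
  continent-specific effects.
- The counterfactual is within-sample by design; it says nothing about
  unsampled locations or future climates.
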