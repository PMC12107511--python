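# beeland

Hierarchical Bayesian analysis of bumble bee occurrence under interacting
land-use, pesticide and climate pressures, run end to end on a fully
synthetic study system with known ground truth.

## The problem

Continental compilations of field surveys (studies × sites × species, with
absences inferred within studies) are the main evidence base for how insect
biodiversity responds to human pressure. For bumble bees the interesting
questions are interactive: does landscape natural habitat matter more inside
farmed land? Does pesticide load bite hardest in the natural habitats next
to farmland? Does warming hurt populations near the hot edge of their
thermal niche? Answering them requires stitching together very different
data products — land-cover rasters, centuries of land-use reconstruction,
monthly climate series, pesticide application maps with toxicity data —
into per-site covariates, then fitting one occurrence model over all of it.

This package implements that whole chain as tested, reusable code, and —
because the real survey compilation cannot be redistributed — ships a
synthetic-data generator that emulates every input format and simulates
occurrence from the very model the pipeline fits, with known coefficients.
That turns the pipeline into a measurable object: parameter recovery,
diagnostic calibration and counterfactual arithmetic are all checked
against ground truth.

## The model

For species *s* at site *j* of study *k*:

```
y ~ Bernoulli(p),   logit(p) = x'β + u_study(k) + u_site(j) + u_species(s)
```

The 15-column fixed-effect design crosses a natural/human local land-use
indicator with: landscape natural habitat (2-km grain), ln(pesticide toxic
load + 1), years since the landscape was 30 % converted to human use, the
species' baseline thermal-niche position (raw quadratic), the warming-driven
shift in that position, plus ln(elevation + 2) as a control. Priors are
weakly informative (Normal(0,5) slopes, Student-t(3,0,2.5) intercept,
half-t(3,0,2.5) random-effect SDs); the posterior is drawn by an exact
Pólya-Gamma-augmented Gibbs sampler, 4 chains × (1000 warmup + 1000 kept).
Diagnostics: split-Rhat, marginal/conditional Bayes R², and permutation
Moran's I tests on site-level residuals (overall and per study). A
posterior counterfactual compares predicted occurrence against a
pressure-free reference (fully natural landscape, no modification history,
no pesticides, no climate-driven niche shift) and reports percentage
reductions by land-use class with 67 %/95 % intervals.

See `docs/methods.md` for the full specification and design choices.

## Worked example

The numbered scripts under `analysis/` run the study start to finish and
write tables under `results/` (bulky intermediates go to `scratch/`):

```bash
python analysis/01_simulate_world.py --seed 1   # world + survey
python analysis/02_build_covariates.py          # covariates + sensitivity grid
python analysis/03_assemble_dataset.py          # outcomes, absences, scaling
python analysis/04_fit_model.py                 # 4-chain Gibbs fit + diagnostics
python analysis/05_counterfactual.py            # pressure-free comparison
```

With seed 1, step 03 reports a survey of 4,050 fitted species × site rows
at 42 % prevalence and a land-use/habitat ANOVA R² of 0.085 — local class
and landscape habitat are nearly independent, so both are estimable. Step
04 prints the forest-plot table; every true generative coefficient falls
inside its 95 % credible interval, e.g. (medians, truth in brackets)
natural habitat +0.61 [+0.50], ln toxic load −0.52 [−0.45], modification
duration −0.45 [−0.35], and the human-land-use × niche-shift interaction
+0.48 [+0.45]; Bayes R² is 0.27 marginal / 0.33 conditional and the overall
Moran's I on residuals is −0.010 (p = 0.056), i.e. no coherent residual
spatial structure. Step 05 then prints the counterfactual:

```
percentage reduction in mean occurrence probability vs pressure-free reference
(local land-use class kept at observed value):
land_use_class  median  lo95  lo67  hi67  hi95
       natural   52.28 48.49 50.47 53.48 54.60
human_modified   50.36 37.72 45.35 54.29 56.81
           all   51.41 44.99 48.83 53.51 55.05
```

read as: given the harmful pressure coefficients the world was generated
with, the pressures have roughly halved mean occurrence probability in both
sampled natural and human-modified habitats, with the wider interval in
human habitats reflecting the offsetting interaction terms.

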