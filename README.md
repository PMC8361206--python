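# stacksdm

Stacked species distribution modelling (S-SDM) for assemblage-level
biodiversity prediction, exercised end to end on synthetic landscapes with
known ground truth.

## The problem

Species distribution models (SDMs) predict where individual species can
occur from environmental covariates. Community ecologists *stack* many
per-species SDMs to predict assemblage properties — how many and which
species co-occur in a grid cell, a vegetation plot, or a survey site — and
then ask how faithful those stacked predictions are to independent
presence/absence surveys, and whether they recover the assemblages'
phylogenetic structure. Evaluating such a workflow on real data confounds
model error with data error; `stacksdm` therefore pairs the full workflow
with a synthetic-data generator in which the true occurrence probability of
every species in every cell is known, so every stage can be tested against
ground truth.

The package provides, as composable library modules with a thin CLI:

- **synthetic data** — spatially autocorrelated covariate rasters, monthly
  climate stacks, virtual species with Gaussian (logit-quadratic) niches
  evolved along a simulated phylogeny with tunable niche conservatism,
  biased presence-only sampling, and nested plot-within-site surveys with
  imperfect detection;
- **covariates** — the 19 bioclimatic variables (BIO1–BIO19) from monthly
  temperature/precipitation rasters, LAI annual-cycle composites,
  integer-factor downscaling, and layer similarity (Schoener's *D*,
  Spearman's ρ);
- **occurrences** — spatial thinning (randomized repeated elimination with
  a record-count-dependent distance rule), buffered bounding-box accessible
  areas, and pseudoabsence sampling;
- **sdm_bart** — probit Bayesian additive regression trees (BART: sum of
  trees, regularizing priors, backfitting MCMC with latent-variable
  augmentation), AUC/TSS evaluation, TSS-maximizing thresholds, covariate
  importance and backward-elimination covariate selection;
- **stacking** — binary (bS-SDM), probability (pS-SDM) and
  probability-ranking-rule (cS-SDM) stacks, plot→site aggregation, and
  stacked uncertainty maps;
- **assemblage evaluation** — SR deviation, SR change, prediction success,
  TSS and Sørensen similarity, for binary and probabilistic predictions;
- **phylostructure** — mean pairwise phylogenetic distance (MPD) and its
  standardized effect size (SES) under a taxon-shuffle null, with exact
  enumeration on small trees;
- **bayes_stats** — robust Bayesian correlation (bivariate Student-t),
  hierarchical Bayesian ANOVA with a unit random intercept, MAP p-values
  and ROPE percentages.

## Core quantities

For an assemblage with confusion cells *a* (both present), *b* (predicted
only), *c* (observed only), *d* (both absent):

    prediction success = (a + d) / (a + b + c + d)
    TSS                = a/(a + c) + d/(b + d) − 1
    Sørensen           = 2a / (2a + b + c)

Richness agreement uses SR change (predicted − observed) and SR deviation
(|predicted − observed| / max observed richness). Phylogenetic structure
uses SES-MPD = (MPD_obs − mean MPD_null) / sd MPD_null with tip-shuffle
nulls. The per-species model is probit BART: P(presence | x) = Φ(Σ_j g_j(x))
with each g_j a regularized regression tree sampled by MCMC.

## Worked example

Run the reference synthetic experiment (32×32 km landscape, 8 species, 10
sites × 6 plots, reduced BART settings) and inspect the scale comparison:

```python
from stacksdm import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(master_seed=2))
for key, value in sorted(result.summary.items()):
    print(f"{key}: {value:.3f}")
corr = result.stats["richness_correlation_site"]
print(f"site-scale Bayesian rho: {corr.rho_median:.2f} "
      f"[{corr.ci_low:.2f}, {corr.ci_high:.2f}]")
```

prints

```
mean_sorensen_plot_bs: 0.495
mean_sorensen_site_bs: 0.861
mean_sr_change_plot_bs: 2.350
mean_sr_change_site_bs: 0.700
richness_pearson_plot_bs: 0.465
richness_pearson_site_bs: 0.831
site-scale Bayesian rho: 0.76 [0.16, 0.93]
```

Predicted assemblages agree with the observed survey much better at the
site scale than at the plot scale (higher Sørensen and richness
correlation), and the binary stack overpredicts plot richness by ~2.4
species on average — the model is denied the fourth, "microhabitat"
covariate that the true niches use, so it predicts the broader envelope a
plot-scale survey does not realize. Both are the qualitative signatures
expected of stacked SDMs evaluated against nested surveys.

The same experiment is available from the shell:

```
stacksdm run-all --seed 2 --out runs/demo
```

which writes rasters, community matrices, evaluation reports, SES-MPD
tables and a manifest of seeds and file checksums under `runs/demo/`.

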