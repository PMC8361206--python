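# Methods

This note documents the models, conventions and design choices behind
`stacksdm`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic study system

The generator produces the study conditions for every downstream test.

**Landscape.** Covariate layers are Gaussian white noise convolved with a
Gaussian kernel of scale `autocorr_range` (km) and standardized to mean 0,
sd 1 — a simple, seedable random field whose lag-1 Moran's I is positive
whenever the range exceeds the cell size and ≈0 at range 0. Monthly
climate stacks (12 × tmin, tmax, precipitation) are built from smooth base
fields (annual mean temperature 12 ± 4 °C, seasonal amplitude 10 ± 2 °C,
diurnal/monthly spread ~8 °C, precipitation ~80 mm month⁻¹, lognormal
spatial variation) modulated by a shared sinusoidal cycle peaking mid-year.
They exist so the bioclim module has realistic, internally consistent
inputs (tmax ≥ tmin, precip ≥ 0); they are not meant to mimic any
particular sensor product.

**Virtual species.** Each species responds to every covariate through a
Gaussian niche on the logit scale: logit p(x) = intercept − Σ_k (x_k −
o_k)² / (2w²), with width `w = 1.2` covariate-sd units (unimodal responses,
the standard virtual-species construction). Niche optima evolve along a
pure-birth (Yule) phylogeny: per covariate the tip optima are
√s · BM + √(1−s) · iid, each term standardized across tips, where BM is a
Brownian-motion realization on the tree and `s = phylo_signal` ∈ [0, 1].
s = 0 gives independent niches; s = 1 maximal niche conservatism (Mantel
correlation between niche and cophenetic distances > 0.3 at n = 40). The
intercept is calibrated by bisection so the landscape-mean probability
equals `prevalence_target` (default 0.25, a mid-prevalence forest-tree
scenario). dendropy's birth-death simulator stops at the speciation event
that creates the n-th tip, leaving two zero-length pendant edges; the
generator extends all pendant edges by the next exponential waiting time,
keeping the tree ultrametric with strictly positive branch lengths.

**Occurrences and surveys.** Presence-only records are cell draws with
weight ∝ true probability × exp(bias_strength · G) for a smooth
standardized field G (multiplicative sampling bias), jittered uniformly
within the cell. True presence grids are independent Bernoulli draws from
the probability surfaces. Surveys nest `plots_per_site` plots uniformly
inside square sites placed uniformly in the landscape; plot incidence is
true presence at the plot's cell thinned by `detection_prob`, with the
detection uniforms drawn independently of the detection probability so
raising it can only add detections (monotone coupling). Site matrices are
the species-wise union over member plots.

**What the generator does not emulate:** real sensor noise or gridded
product artefacts, geographic coordinate systems (all distances are planar
km), temporally varying ranges, biotic interactions, or abundance.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative behaviour of the workflow under known truth, not performance on
any particular real data set.

**Reference fixture.** The default pipeline configuration is a 32 × 32 km
landscape (1-km cells, 4-km autocorrelation), 4 covariates, 8 species with
phylo_signal 0.7, 150 records per species with bias strength 0.5, 10 sites
× 6 plots (5-km sites, detection 0.9), and reduced sampler sizes (below).
The model is denied covariate `cov4` while the truth uses it, emulating an
unobserved microhabitat axis; this is what produces the plot-scale
overprediction the worked example shows. Sizes were chosen so the full
experiment runs in seconds while leaving enough units (60 plots, 10 sites)
for correlations across units to be meaningful.

## Bioclimatic covariates

BIO1–BIO19 follow the standard formulas with monthly mean temperature
(tmin + tmax)/2 and *wrap-around* 3-month quarters (all 12 contiguous
windows including Dec–Jan–Feb), the ANUCLIM/`biovars` convention; the
choice matters for BIO8–BIO11 and BIO16–BIO19. Quarter selections take the
first window attaining the extreme. Standard deviations use the sample
convention (ddof = 1). BIO15 defaults to the "plus-one" dialect
100·sd(p)/(1 + mean(p)), finite for all-zero precipitation and matching the
widely used `biovars` implementation; a `raw` dialect (100·sd/mean) is a
config switch. BIO3 is set to 0 where BIO7 = 0 (isothermal degenerate
case). The raster implementation is verified cell-by-cell against an
independent scalar reimplementation of the formulas.

LAI composites are defined on the per-month climatology (mean over years):
cumulative = annual sum, minimum = cell-wise minimum, seasonality = CV (%)
of the 12 climatology values. The source workflow names these composites
without formulas, so these definitions are interpretations, chosen as the
simplest annual-cycle summaries with the stated names.

Downscaling refines each cell into `factor`² cells; `nearest` replicates
values (preserving the value multiset), `bilinear` interpolates between
input cell centres with edge clamping, reproducing linear gradients exactly
away from the half-cell border. Both are provided because the original
workflow does not name its resampling method.

Schoener's D treats each layer as a spatial density: min-shift to
non-negative, normalize to sum 1, D = 1 − ½Σ|p_a − p_b|. An all-constant
layer is treated as a uniform density; Spearman's ρ is reported missing
(with a warning) when either layer is constant. D is symmetric and
invariant to positive affine rescaling of either layer.

## Occurrence preparation

The thinning distance is 1 km below 100 records and 5 km above 10,000,
log-linear in log10(n) between (1 + 2·(log10 n − 2) km); the interior
schedule is an interpretation since only the endpoints are stated by the
source workflow. Thinning itself is randomized repeated elimination
(default 25 passes, best pass kept): repeatedly remove a random record
among those with the most remaining neighbours closer than the distance.
Exact maximum retention is NP-hard; exactness is asserted only against
brute-force enumeration on small instances. Thinning is idempotent and
per-species.

The accessible area is the record bounding box buffered by 300 km per side,
clipped to the landscape when supplied. Pseudoabsences equal the presences
in number ("similar to" implemented as exactly equal, for
reproducibility), drawn uniformly without replacement from valid cells
inside the accessible area excluding presence cells (exclusion at cell
resolution).

## Probit BART

Binary outcomes enter through the Albert–Chib latent-variable scheme:
z_i ~ N(f(x_i), 1) truncated above/below 0 by the label, f a sum of `m`
trees updated one at a time against the latent residuals (backfitting
MCMC). Priors are the standard regularizing choices: split probability
α(1+d)^−β at depth d with α = 0.95, β = 2; splitting rules uniform over
variables and a ≤100-point per-variable quantile cutpoint grid; leaf values
N(0, σ_μ²) with σ_μ = 3/(k√m), k = 2, shrinking f into roughly (−3, 3).
Tree proposals are grow/prune/change at 0.4/0.4/0.2 with leaf values
integrated out analytically in the Metropolis–Hastings ratio; the swap move
is omitted (minor, as in several production implementations), `change` is
restricted to internal nodes with two leaf children (symmetric proposal),
structurally impossible moves count as rejections, and proposals creating
empty leaves are rejected. Reference settings are 200 trees × 1000
iterations with 20% burn-in; the reduced configuration used by tests and
the pipeline (`BARTConfig.test_size()`) is 20 trees × 200 iterations, which
reaches AUC ≥ 0.95 on the 300-point separable fixture in well under a
second. Everything is deterministic given the seed.

Numerical notes: the truncated-normal draw uses the inverse-CDF form with
the argument clipped to [1e−12, 1−1e−12]; predictions are Φ(f) averaged
over retained draws, with the 95% credible-interval width the 2.5–97.5
posterior percentile range. Models serialize to JSON-lines (one header, one
line per retained draw).

**Flat extrapolation.** A sum of trees is piecewise constant: cells beyond
the last cutpoint inherit the boundary leaves' posterior, so credible
intervals neither inflate nor collapse under covariate extrapolation —
unlike Gaussian-process-style models. The tests assert the true property
(positive width, comparable to the nearest in-range cells); users should
not read the uncertainty maps as warning about environmental novelty.

**Prevalence identifiability.** With presence + equal-pseudoabsence
training the 1:1 class balance pins every species' predicted base rate near
0.5; prevalence is not identifiable from presence-only data, a known
property of the design, and no transform of such predictions recovers
prevalence ranks. Calibration-level recovery (true vs predicted landscape
prevalence, rank correlation ≈ 1 across 10 virtual species) is therefore
demonstrated with Bernoulli presence/absence survey labels; the pipeline
itself keeps the presence + pseudoabsence design of the workflow it
implements.

Evaluation: AUC is the Mann–Whitney rank statistic with half credit for
ties; the TSS threshold is the smallest of the sorted unique predicted
values maximizing sensitivity + specificity − 1 (binarization rule p ≥ t).
Covariate importance is the share of splitting rules using each covariate
across retained draws (uniform if the ensemble happens to contain no
splits). Covariate selection is backward elimination by importance with a
4-fold stratified cross-validated AUC stopping rule (default tolerance
0.01) — the selection internals of the original tooling are unstated, so
this rule is an interpretation, recorded in the returned trace.

## Stacking

bS-SDM sums thresholded binary layers; pS-SDM sums probabilities (expected
richness); cS-SDM applies the probability ranking rule per unit with the
unit's *observed* richness as the constraint (the per-assemblage reading of
the richness cap — consistent with SR deviation/change not being computed
for cS-SDM, whose richness is fixed by construction). PRR ties break
alphabetically by species id for reproducibility; a seeded random
tie-break is available. Plot→site aggregation is species-wise union for
binary/PRR and species-wise max for probabilities (probability in the best
plot); a noisy-or rule (1 − Π(1−p)) is a config alternative. At the site
scale cS-SDM re-ranks the aggregated probabilities against observed site
richness rather than unioning plot-level selections. The stacked
uncertainty map is the per-cell sum of per-species credible-interval widths
— the source figure never defines its uncertainty quantity, so this sum is
a documented interpretation.

## Assemblage evaluation

Binary predictions give counting confusion cells; probabilistic ones give
expected cells (a = Σp over observed-present, etc.), the community-ecology
convention for evaluating probability stacks. Prediction success, TSS and
Sørensen follow the formulas above; TSS is reported missing with a warning
when a margin is degenerate (no observed presences or no observed
absences). Units are matched by id; species columns are outer-joined with
zero fill (logged, since unrecorded species inflate the both-absent cell).
SR deviation scales by the maximum observed plot richness of the survey.

## SES-MPD

MPD is the mean cophenetic distance over unordered present–present pairs
(undefined below 2 species). The null shuffles the tip labels of the
distance matrix over the full tree tip pool, holding richness fixed; the
pool choice is a config-visible consequence of shuffling "the tips of the
phylogeny" (shuffling only observed species would change SES). Because a
uniform tip permutation maps a richness-k assemblage to a uniform random
k-subset, trees with ≤7 tips are enumerated exactly (population sd over all
C(n, k) subsets); larger trees use seeded Monte-Carlo permutations
(default 999; pipeline 499) with sample sd and rank p-value
(#{null ≤ obs}+1)/(n_null+1). SES = (obs − null mean)/null sd, flagged
undefined when the null sd is 0 (e.g. a star tree). Under this formula
single-clade (clustered) assemblages get SES < 0 and cross-clade
(overdispersed) assemblages SES > 0; the literature is split on which sign
is *called* "clustering", so users comparing against other software should
check the sign convention rather than the magnitude, which is invariant to
branch-length rescaling.

## Bayesian comparisons

*Robust correlation*: bivariate Student-t likelihood with free location
pair, scale pair, correlation ρ and degrees of freedom ν (fixable, e.g.
ν → ∞ for a plain-normal fit). Priors: N(sample mean, (10·sd)²) locations,
half-normal(10·sd) scales, uniform(−1, 1) ρ, ν − 1 ~ Exponential(mean 29).
Sampling is joint random-walk Metropolis on transformed parameters (log
scales, atanh ρ, log(ν−1)) with Robbins–Monro step adaptation during
burn-in, 4 chains (default 10,000 iterations, 20% burn-in; tests use
1,000). Reported: posterior median ρ, central 95% interval, and
rank-normalized split R-hat (via arviz).

*Hierarchical ANOVA*: value = intercept + group effect (treatment coding) +
unit random intercept + noise, the repeated-measures correction for units
scored under several stacking procedures. All full conditionals are
conjugate (vague normal fixed effects with precision 1/(100·var_y);
inverse-gamma(2, var_y) noise and random-intercept variances), so the
sampler is Gibbs — chosen over random-walk Metropolis because the unit
intercepts make the space high-dimensional. Group contrasts are reported
per pair with MAP p-values and ROPE percentages.

*MAP p-value*: Gaussian KDE with Silverman bandwidth; density at 0 over
density at the mode (located on a 512-point grid over the draw range),
clipped to [0, 1]. *ROPE*: percentage of draws inside [low, high]; the
default bounds are ±0.1 response sd (the common standardized default — the
source workflow does not state its bounds).

## Pipeline and reproducibility

Stage seeds derive deterministically from the master seed via spawned
`SeedSequence`s, so identical configurations produce byte-identical
artifacts (asserted via manifest checksums). All artifacts are text: ESRI
ASCII grids for rasters, CSV for tables, Newick for trees, JSON for
summaries and the manifest. A stage failure aborts with the stage name and
leaves a `FAILED` marker beside any partial outputs. Robust correlations
are skipped (reported missing) when a scale has constant observed or
predicted richness, which can happen in very small smoke configurations.

## Known limitations

- Planar geometry only; no CRS handling or great-circle distances.
- The BART sampler matches the standard construction at the level of
  contracts and recovery behaviour, not the numerics of any particular
  implementation; the swap move is omitted and degenerate-state proposal
  probabilities are nominal.
- Flat extrapolation of tree ensembles (above).
- Incidence data only: no abundance weighting in MPD, no occupancy-model
  treatment of imperfect detection.
- The LAI composite formulas, interior thinning schedule, stacked
  uncertainty map, PRR site-scale re-ranking and ROPE bounds are documented
  interpretations where the source workflow is silent.
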