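# Methods

`antscape` implements the quantitative chain from raw nested ant-nest survey
counts to community-level inference: integrated nest densities, Hill-number
evenness, multivariate count models of environmental heterogeneity effects,
and penalized trait-environment (fourth-corner) models. This note documents
the models, the defaults, and the choices made where the design was open.

## Survey model: recording groups and pseudo-areas

A survey unit ("Seifert-plot") nests three search levels: scrutiny (S, fixed
64 m²), quick search (Q, fixed 400 m²), and spot inspection (SI, variable,
around 900 ± 82 m²). Species are assigned to *recording groups*, each a
triple of detection weights (w_S, w_Q, w_SI) ∈ [0,1]³ giving the probability
that a nest of that group is found at each level. The *pseudo-area* of a plot
for a group is the detectability-weighted searched area in 100 m² units:

    PA = (w_S·A_S + w_Q·A_Q + w_SI·A_SI) / 100

The integrated density of a species over a site's plots is the summed nest
count across all levels and plots divided by the summed pseudo-area of its
group — nests per 100 m², comparable across species of different
perceptibility. The count-model offset is the natural log of the arithmetic
mean of the per-group site pseudo-area sums.

Open choices, resolved as follows:

- **Recording-group weights.** Published group calibrations are external to
  this package; groups are supplied via `recording_groups.csv`. The three
  shipped defaults — conspicuous (1,1,1), intermediate (1,1,0), cryptic
  (1,0,0) — are illustrative placeholders spanning the detectability
  spectrum, not published values.
- **Offset averaging.** Whether the "mean pseudo-area" averages over groups
  or species is a genuine ambiguity; both are implemented
  (`offset_mode: by_group | by_species`). The default averages over distinct
  recording groups so the offset does not depend on species richness.
- **Empty sites** are retained in the density matrix (all-zero rows, flagged)
  but excluded from count models, where they contribute a degenerate
  likelihood.

## Diversity and evenness

Hill numbers qD are effective species numbers: 0D = richness, 1D = exp of
Shannon entropy, 2D = inverse Simpson concentration. Relative logarithmic
evenness RLE₀,₂ = ln(2D)/ln(0D) equals 1 for a perfectly even community and
requires ≥ 2 species (ln 0D = 0 otherwise; such sites are excluded from
evenness models with a logged note). Classification thresholds: even at
RLE ≥ 0.65, dominated at RLE ≤ 0.45, uneven between — boundaries assigned
per the printed inequalities. All logarithms are natural (RLE is
base-invariant; the landscape Shannon index is reported in nats).

Note the true range of RLE for ≥ 2 species is (0, 1]: 2D ≥ 1 always, so the
ratio can fall below 1/0D under strong dominance (e.g. densities (1, 5) give
RLE ≈ 0.469 < 0.5); 1/0D is only the approximate location of the dominated
regime, not a bound.

## Exploration

Collinearity is screened by pairwise Pearson |r| ≥ 0.7 on numeric predictors
(constant columns are skipped with a warning). Ward minimum-variance
clustering runs on raw site density coordinates via
`scipy.cluster.hierarchy.linkage(method="ward")` — operating on coordinates
rather than a precomputed distance matrix resolves the classical
ward.D/ward.D2 ambiguity in favor of the internally consistent
increase-in-variance criterion. Candidate partitions k = 2..min(10, n−1) are
scored by mean silhouette width; singleton clusters contribute silhouette 0
(sklearn's convention, adopted as the documented choice). An optional log1p
transform is available for clustering but off by default, since densities
are the analysis entries.

## Multivariate negative-binomial GLMs

One NB regression per species over a shared design with the survey offset:

    log μ_ij = offset_i + x_i'β_j,  y_ij ~ NB(μ_ij, θ_j)

Continuous predictors are z-scored (recorded in fit metadata); categoricals
are dummy-coded against the first sorted level, so `meadow` is the reference
for management. Dispersion θ_j is estimated per species by ML jointly with
β_j: iteratively reweighted least squares for β given θ, alternated with
Newton steps on log θ, converged on relative log-likelihood change < 1e-9.
The fitter is batched — many (species × bootstrap-replicate) responses
sharing one design are solved simultaneously with vectorized per-response
normal equations — which is what makes resampling-based inference fast
enough to be routine. Against statsmodels' NB ML on the same design the
batched fitter agrees to ~1e-5 in coefficients and log-likelihood.

- **AIC**: per species −2ℓ + 2(p+1), counting θ; community total is the sum.
  Backward elimination drops the term whose removal most lowers total AIC,
  ties broken by listing order; the intercept is never dropped.
- **Sum-of-LR test**: the community statistic for a term is
  2Σ_j(ℓ_full,j − ℓ_reduced,j). Its null distribution comes from a
  parametric bootstrap (default 999 resamples): new count matrices are drawn
  from the fitted reduced model and both models refitted;
  p = (1 + #{LR* ≥ LR})/(B + 1), so p is bounded below by 1/(B+1).
  By default species are resampled independently; a Gaussian-copula option
  shares one standard-normal draw per site across species (mapped through
  each species' NB quantile function) to induce cross-species correlation in
  the null — the claim that parametric bootstrap "accounts for correlation
  across species" is ambiguous, so both readings are available and the
  independent one is default.
- **Diagnostics**: Dunn–Smyth (randomized quantile) residuals,
  Φ⁻¹ of a uniform draw between the NB CDF at y−1 and y; approximately
  standard normal under a correct model. Seeded explicitly, like every other
  source of randomness; there is no global random state.

Degenerate inputs: all-zero species are dropped with a warning; all-zero
sites must be filtered upstream (the pipeline does this); all-zero bootstrap
responses are handled by clipping the linear predictor at ±30, which drives
their likelihood contribution to its boundary limit smoothly.

## Beta regression of evenness

RLE is modeled with a beta likelihood, logit mean link, and a single
constant precision φ (no precision covariates), using statsmodels'
`BetaModel` behind the module surface. Responses touching 0 or 1 — possible
in synthetic data, not in the emulated survey — are compressed by
(y(n−1) + 0.5)/n, applied only when a boundary value is present and logged.
Nested models are compared by 2Δℓ against χ²; backward AIC selection mirrors
the count models with scalar AIC = −2ℓ + 2(p+1).

## Fourth-corner and multispecies distribution models

Counts are stacked into one row per (site, species) cell and fitted as a
single NB regression with log link and the offset:

    log μ_ij = offset_i + a_j + x_i'b + x_i'Γ'τ_j

with species intercepts a_j, environment main effects b, and the
traits × environment interaction matrix Γ (the fourth corner). In SDM mode
the trait matrix is the species indicator matrix, giving species-specific
environmental responses, and the env mains are omitted (collinear with the
full indicator interaction); passing an indicator trait table to the
fourth-corner builder with standardization off reproduces the SDM design
exactly.

Only the interaction block is L1-penalized; species intercepts and env mains
stay unpenalized, keeping the "different species, different baselines"
structure identifiable. The penalized likelihood (−ℓ/N + λ‖Γ‖₁) is
minimized by FISTA with backtracking and restart; soft-thresholding yields
exact zeros. Numerical choices:

- λ grid: 50 points log-spaced from λ_max (the largest absolute penalized
  score component at the unpenalized-backbone fit, below which the first
  interaction enters) down four decades; fits warm-start along the path.
- Cross-validation: 5-fold, stratified by site (all cells of a site share a
  fold); λ* maximizes mean held-out NB log-likelihood per cell, ties resolved
  toward the sparser λ.
- Dispersion θ is estimated once from the unpenalized backbone, held fixed
  along the path for stability at small n, then re-profiled at λ* before the
  final polish.
- Pseudo-R² is McFadden's 1 − ℓ/ℓ₀ against the species-intercepts-only
  model; other R² flavors used by figure captions elsewhere are not
  derivable and are treated as non-targets.

## Synthetic survey generator

The generator emulates the study conditions: 33 grassland sites (21 pasture,
12 meadow), 1–3 plots per site (weights 0.4/0.4/0.2), a 16-species pool,
SI areas ~ N(900, 82²) m². Continuous environmental covariates are drawn
from triangular distributions pinned to the published min/median/max
summaries (e.g. wetness variation 3.7/11.7/30.1%). Land covers come from a
Dirichlet simplex with a fifth untracked slack component, so the four
reported covers do not sum to exactly 100 (matching field tables whose
recorded classes need not exhaust the buffer) and remain below the
collinearity threshold in most draws; the landscape diversity column is the
Shannon index recomputed from those covers, keeping the table internally
consistent. Because forest cover dominates the composition, forest cover and
landscape diversity still exceed |r| = 0.7 in occasional draws — a
structural feature of compositional data that the screen is there to flag.

Counts follow the analysis model read backwards: site totals are NB with
log-mean = log(site pseudo-area) + α_j + x_i'(β_j + Γ'τ_j), species
baselines α_j ~ N(ln 0.35, 0.8²) so whole-community site densities land in
the observed few-per-100 m² range, θ = 1.5. Totals are split across plots in
proportion to plot pseudo-areas and across S/Q/SI levels with probabilities
∝ w_level·A_level, conserving totals exactly. Per-species environmental
responses default to zero (`env_effect_sd` turns them on); the fourth-corner
component is an explicit dict of trait×env entries.

Not emulated: between-covariate correlation structure of real landscapes,
spatial arrangement of sites, dispersal or colonization dynamics, and
observer error beyond the detectability weights. Passing tests on generated
data therefore demonstrate correctness of the estimators under the assumed
data-generating process, not robustness to field-data pathologies.

The roundtrip check compares integrated densities recovered by the survey
module against the generator's true expected densities. Cellwise rank
correlation is intrinsically noisy (most cells hold zero or one nest), so
the report gives three views; the per-species pooled correlation is the
meaningful one and exceeds 0.9 at default size.

## Verification scale

The test suite verifies: exact agreement of Hill/RLE analytics with a
brute-force oracle (1000 random communities, 1e-12); the full-detection
density oracle (exact); additivity of the sum-of-LR statistic (50 datasets,
1e-8); calibration of the 199-resample bootstrap at α = 0.05 over 500 null
datasets (binomial 95% interval); parameter recovery for the NB many-GLM
(n = 200 sites), beta regression (n = 500), and the fourth-corner LASSO
(sign of a planted dominance×management interaction in ≥ 19/20 seeds at
n = 200; ≥ 90% exact zeros under a null Γ at n = 100); the offset contract
(doubling pseudo-areas shifts intercepts by −ln 2, 1e-6); and the structural
invariants (Hill monotonicity in order, Ward merge monotonicity, LASSO
sparsity monotone in λ, bootstrap p ≥ 1/(B+1)).

## Known limitations

- Recording-group weights and species→group assignments must be supplied;
  the shipped defaults are placeholders.
- The bootstrap refits θ per resample by the same profile iteration as the
  observed fit; no small-sample correction is applied beyond the +1
  convention in the p-value.
- The stepwise search is greedy backward elimination; it does not enumerate
  interactions on its own (interaction terms may be listed explicitly as
  `a:b`).
- The beta regression models a constant precision only.
- FISTA convergence is to 1e-9 relative objective change; coefficients near
  the selection boundary at λ* can differ in the last ~1e-4 between warm and
  cold starts.
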