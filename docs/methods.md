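# Methods

## Scope and model structure

`ddaffinity` estimates, per species-site cell of a binary metacommunity
matrix, the joint tendency of the species to be absent from suitable sites
and of the site to lack suitable species (dark-diversity affinity, DDA).
The model assumes:

- occupancy cells are conditionally independent Bernoulli draws given the
  cellwise presence likelihood `p`;
- the species-side and site-side affinities are deterministic logit-linear
  functions of observed traits/attributes (no entity-level random effects by
  default; an optional shared intercept switch exists, residual terms do
  not — the per-entity posterior spread therefore reflects coefficient
  uncertainty only);
- suitability is an input fixed before fitting (estimated from
  co-occurrence, or supplied externally), not a parameter of the posterior;
- the balancing constant δ is computed once from the data
  (`logit(mean(prab)) − logit(0.5·mean(suit))`) and held fixed during
  sampling.  When DDA is neutral (0.5 everywhere) and suitability constant,
  these definitions make `p` equal the observed prevalence exactly; this
  algebraic identity is tested to machine precision.

## Suitability

For species i, j with occupancies `n_i`, `n_j` over `N` sites, the observed
co-occurrence `C_ij` is standardized by the hypergeometric moments
`μ = n_i n_j / N` and `σ² = n_i n_j (N−n_i)(N−n_j) / (N²(N−1))`; pairs with
`σ² = 0` (a species absent everywhere or present everywhere) get SES 0.  A
species' raw score at a site is the unweighted mean SES over the *other*
species present there (0 when it would average over nothing).  Two monotone
maps to [0, 1] are provided and are rank-equivalent by construction:

- `minmax` (default): rescale by the metacommunity-wide minimum and maximum,
  attaining the full 0–1 range;
- `normcdf`: the standard-normal CDF of the raw score, which maps the empty
  average to 0.5 and is robust to outlying scores.

The exact aggregation and truncation conventions used by other
species-pool estimators differ between implementations; keeping the map a
configuration choice records that genuine freedom instead of hard-coding one
convention.  Both dialects are checked cell-by-cell against a brute-force
double-loop implementation whose hypergeometric moments come from exhaustive
subset enumeration (feasible for N ≤ 8).

## Priors, design, and identifiability

Quantitative predictors are standardized to mean 0 and sample (n−1) SD 0.5,
so a coefficient of b is the logit change across two predictor SDs and is
comparable with binary-indicator coefficients.  Categorical predictors are
expanded to one 0/1 indicator per declared level with *no* dropped
reference, so each level's coefficient is a deviation from the intercept;
the resulting soft collinearity (indicators of one trait sum to the
intercept column) is resolved by the shrinkage priors.  Priors are
independent normals with mean 0, SD 0.5 on intercepts and SD 2.5 on slopes —
weakly informative on the logit scale at this predictor scaling.  The two
submodels get separate intercepts `a_sp` and `a_site`; only their mean
enters the unified DDA, so each is partially prior-identified — a
`shared_intercept` switch collapses them for sensitivity analysis.  Constant
predictors are dropped with a warning rather than failing the run.

Blocks of related environmental variables can be summarized by the first
principal component of their correlation matrix (variables z-scored first,
so the scores are invariant to per-variable affine rescaling), sign-aligned
so the score-variable correlations sum positive; the scores then enter the
design like any quantitative predictor and are re-standardized with it.

## Sampling and convergence

The posterior over the coefficient vector is sampled with an adaptive
random-walk Metropolis kernel: during burn-in, a global proposal scale is
tuned toward the 0.234 multivariate target acceptance rate and the proposal
covariance tracks the running chain covariance (scaled 2.38²/d); adaptation
freezes when sampling starts, so retained draws come from a
time-homogeneous chain.  Defaults follow a 3 × 333 retention schedule
(999 draws) with burn-in 4000 and thinning 12; if any parameter's classic
Gelman–Rubin factor exceeds 1.1, burn-in and thinning are doubled and the
fit rerun, up to the 25000/75 ceiling, after which the results carry an
explicit `converged = False` flag — never a silent acceptance.  All
randomness flows from one `SeedSequence`, so a fixed seed reproduces every
retained draw bit for bit (the CLI stages are byte-deterministic).  A unit
test cross-checks posterior quartiles against an independent
affine-invariant ensemble sampler, and an acceptance test checks the
intercept-only posterior against deterministic 2-D grid integration of the
identical joint density (medians within 0.02).

Derived quantities (`dda_sp`, `dda_site`, cellwise DDA and `p`) are
recomputed deterministically from the coefficients of each retained draw.
Logit arguments are clamped to [ε, 1−ε] with ε = 10⁻⁶ (configurable in
(0, 0.01)) because min-max suitability attains exact 0 and 1.

## Summaries and tests

Posterior summaries use type-7 (linear interpolation) quantiles; this is
documented because classifications at a credible-interval edge can flip
under other quantile types.  An entity is `dark-affine` when its central
95% interval lies wholly above 0.5, `presence-affine` below, `unresolved`
otherwise.  Coefficients are reported by posterior mean and flagged
significant when the interval excludes 0.

Absent/present subset comparisons use the tie-corrected Kruskal–Wallis H
with the χ² approximation; all-tied data returns H = 0 by convention rather
than erroring.  The sampling unit is one posterior *median* per cell (or per
entity, broadcast to its cells) — pooling all draws as observations would
inflate the sample size of the rank test roughly 1000-fold; a `pool_draws`
switch reproduces that pooled alternative for sensitivity, and neither mode
is claimed to be the one used in any particular published table.

## Synthetic data and what passing tests show

The generator inverts the model: standard-normal quantitative traits and
uniform categorical levels, known coefficients, suitability either i.i.d.
Beta(α, β) per cell or a Gaussian niche kernel along a latent gradient, a
*configured* δ (default 0, so closed-form cellwise probabilities exist), and
Bernoulli occupancy.  The standard study conditions used by the recovery
harness and the acceptance script are 60 species × 40 sites, one
species-trait effect +2 and one site-attribute effect −2, suitability
Beta(2, 2), 10 replicates, fitted at burn-in 2000 / thinning 6 — sizes
chosen so a full calibration experiment runs in minutes on one CPU while
each replicate still has 2400 cells of likelihood.  Because the analysis
path recomputes δ from each realized matrix while the generator fixed it,
recovery quantifies that mismatch too.

The generator emulates the *shape* of field survey data (binary matrices
with trait-driven occupancy structure), not its full texture: no sampling
effort variation among hosts, no parasite aggregation among host
individuals, no spatial autocorrelation among sites, and suitability is
either exactly known or exactly the model's co-occurrence construct.
Passing recovery tests therefore demonstrate the estimator's internal
correctness and calibration under the model's own assumptions — not that
field data satisfy those assumptions.

## Data selection

Survey records can be filtered before matrix assembly: records with fewer
than `min_examined` examined host individuals are dropped first (sparse
sampling underestimates presences because parasites aggregate among host
individuals), then species under `min_sites_per_species` and sites under
`min_species_per_site` are removed in a single pass, in that order.
All-zero rows/columns are removed in strict validation before suitability (a
never-observed species has undefined co-occurrence moments), with every
removal logged.

## Known limitations

- Suitability is treated as error-free in the fit; uncertainty in the
  co-occurrence estimate does not propagate into coefficient intervals.
- The two intercepts are only jointly likelihood-identified; their marginal
  posteriors lean on the prior.
- Per-level categorical coefficients are shrinkage-identified; strongly
  unbalanced levels inherit wide intervals.
- The Metropolis kernel is practical into the tens of parameters;
  far larger designs would favour a gradient-based sampler, which the
  fitting contract (target density, retention schedule, R-hat gating,
  seeded determinism) deliberately leaves open.
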