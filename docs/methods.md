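# Methods

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions that were genuinely open.

## Hierarchical spatial logistic model

For a binary outcome on respondents nested in areas,

    Y_i ~ Bernoulli(p_i),   logit p_i = β₀ + x_i'β + f_s(a_i) + f_u(a_i).

Covariates are categorical, dummy-coded against a reference level (by
default the first declared level; configurable per factor, since published
analyses are not always consistent about which region is the reference —
both conventions are one flag away).  The area effects are

- **f_u** — exchangeable heterogeneity: f_u,j ~ N(0, 1/τ_u) iid;
- **f_s** — an intrinsic CAR / intrinsic Gaussian Markov random field on the
  adjacency graph: density kernel exp(−(τ_s/2)·Σ_{i~j}(f_s,i−f_s,j)²) with
  τ_s carrying exponent (m−k)/2, where m is the number of areas and k the
  number of graph components.  The prior is improper (rank m−k); the model
  is identified by a hard sum-to-zero constraint within every component.

Models 1–4 toggle (f_s, f_u) off/on in the four combinations.  Priors:
β₀, β ~ N(0, 1/τ_β) with τ_β = 10⁻⁴ (effectively flat on the odds-ratio
scales of interest); τ_s, τ_u ~ Gamma(shape a = 0.5, rate b = 0.0005), a
standard vague disease-mapping choice when the analysis being reproduced
says only "vague gamma priors".  All are configurable.

### Posterior computation

Inference is by Metropolis-within-Gibbs MCMC.  This is the package's one
deliberate methodological substitution: the disease-mapping literature often
uses nested Laplace approximations for this model class, but MCMC targets
the identical posterior and — unlike an approximation — can be verified
directly against conjugate conditionals and maximum-likelihood oracles,
which is what the test suite does.

- β₀ and each β_j: Gaussian random-walk proposals.  Scales adapt during
  burn-in toward ≈35% acceptance (multiplicative Robbins–Monro update every
  100 iterations, clipped to [10⁻³, 50]) and are frozen afterwards so the
  post-burn-in chain satisfies detailed balance.
- f_u and f_s: single-site random walks.  The ICAR prior contribution for a
  site uses only its neighbour differences.  After each f_s sweep the field
  is re-centred to sum to zero per component and the (area-count-weighted)
  removed mean is folded into β₀, then the likelihood is recomputed; with a
  connected graph this leaves the linear predictor exactly unchanged.
- τ_u ~ Gamma(a + m/2, b + ½Σf_u²) and τ_s ~ Gamma(a + (m−k)/2,
  b + ½Σ_{i~j}(f_s,i−f_s,j)²): conjugate Gibbs draws.

The Bernoulli likelihood depends on a record only through its linear
predictor, so records are collapsed to (area × covariate-pattern) cells once
at setup; every likelihood evaluation is O(#cells), which keeps full fits of
a few thousand respondents to a couple of seconds.

Defaults: 20 000 iterations, 5 000 burn-in, thinning 5; a seed is mandatory
(every stochastic function in the package takes one, and the pipeline
manifest echoes them all).  Divergence (non-finite log-likelihood) aborts
with diagnostics rather than continuing silently.  Requesting f_s on an
edgeless graph is an error: the ICAR prior carries no information there.

### DIC

pD = D̄ − D(θ̄), with D(θ̄) the deviance at the posterior means of the
linear-predictor parameters (β₀, β, f_s, f_u), and DIC = D̄ + pD.  Negative
pD is reported with a warning, not an error.  Exact DIC ties break toward
the model with fewer random-effect components, then toward the earlier
model id — a documented, deterministic rule.

### Posterior prevalence maps

For each stored draw, an area's prevalence is the average of expit(η_i)
over the area's observed records; mean/median/2.5%/97.5% summaries are
taken across draws.  An area with no records is evaluated at the reference
covariate pattern (its own f_s, f_u still apply) and flagged, rather than
dropped.

## Bernoulli spatial scan

Circular windows are grown from every area centroid over areas ordered by
haversine distance (Earth radius 6371 km; distance ties broken by area file
order so results are reproducible).  Nested prefixes are admissible while
their cumulative at-risk total stays within `max_fraction` (default 0.5,
the conventional ceiling; the centre-only window is always admissible).
Note the all-areas window can never be admissible under this rule — a
window containing everything has no outside to compare against, and its
LLR is defined as zero regardless.

The window score is the Bernoulli log-likelihood ratio with the convention
0·ln 0 = 0, set to zero unless the inside rate is on the requested side of
the overall rate: high- and low-rate scans are two separate one-sided
analyses, because high and low clusters are reported separately.

Monte Carlo inference conditions on the total case count C and the area
totals n_i: each replicate deals the C cases across the N individuals
without replacement (multivariate hypergeometric over areas) and rescans.
p = (1 + #{replicate max ≥ observed}) / (1 + replications), so p-values are
never zero and every candidate is referred to the null distribution of the
*maximum*, which is what makes the reported p-values multiplicity-adjusted.
Secondary clusters are selected greedily in LLR order under a strict
no-overlap rule, stopping at the significance level (default 0.05).

The per-area counts fed to the scan are unweighted by default.  A weighted
mode scales weighted sums to preserve the overall respondent count and
rounds by largest remainder (the scan needs integers); rounding never lets
an area's cases exceed its total.  Which convention a published analysis
used is typically unstated, hence both are supported and the pipeline
manifest records the choice.

## Design-weighted estimation

- Prevalence: ratio estimator Σwy/Σw; variance by Taylor linearization with
  stratified, with-replacement between-PSU totals; design df = #PSUs −
  #strata; 95% CI formed on the logit scale and back-transformed (the
  survey-software default; Wald available).  Degenerate estimates (p = 0 or
  1, or zero variance) fall back to a clipped Wald interval.  A stratum with
  a single PSU is an error instructing collapse, not a silent NaN.
- Cross-tabulations: Pearson X² from weighted cell proportions with the
  second-order (Satterthwaite) Rao–Scott correction — generalized design
  effects are eigenvalues of V₀⁻¹V̂ with V̂ the linearized covariance of the
  independence residuals and V₀ their multinomial covariance — referred to
  F(d/(1+a²), ν·d/(1+a²)) with ν the design df.  Under equal weights and
  one PSU per record this reduces to the ordinary chi-square test, which is
  tested explicitly.
- Media-exposure index: items standardized, first eigenvector of the
  correlation matrix, sign fixed so the loading sum is non-negative, scores
  cut at *weighted* tertiles (the cut-point rule is an assumption — source
  analyses rarely state one — with boundary ties going to the lower
  category).  Zero-variance items are excluded with a warning.

## Synthetic survey generator

The generator emulates a two-stage stratified cluster sample of the DHS
type: areas partitioned into contiguous regions, PSUs (enumeration areas)
nested in areas, strata = region × urban/rural, equal-size PSU takes, and
design weights constant within PSU (lognormal dispersion, normalized to
mean 1; dispersion 0 gives exactly unit weights).  A region whose urban or
rural stratum ends up with a single PSU is collapsed to one region-wide
stratum so design-based variances stay estimable.  Outcomes follow the
hierarchical logistic model above with an ICAR f_s drawn via the spectral
pseudo-inverse of the structure matrix and iid f_u.

Default conditions — 8 regions, 4 PSUs per area, 25 respondents per PSU
(≈100 per area, i.e. a few thousand respondents on the 30–47-area maps used
throughout), weight dispersion 0.2, baseline logit −1, a rising age gradient
(0.5, 1.0) and falling education gradient (−0.4, −0.9), τ_s = 2, τ_u = 10 —
are chosen once to mirror, at roughly one fifth scale, the size and effect
pattern of a national survey round over ~47 counties, keeping every test
and the acceptance script fast on one CPU.

What it does **not** emulate: questionnaire content, household rosters,
nonresponse and calibration adjustments, spatially varying sampling rates,
or covariate–area confounding (covariates are sampled independently of area
by default; an area-confounded mode would be a straightforward extension).
Passing tests therefore demonstrate correctness of the estimators and
samplers under a clean design, not robustness to the messiness of real
fieldwork data.

## Validation strategy and problem sizes

The acceptance layer re-derives everything it asserts: the scanner is
checked exactly (LLR to 1e-9) against a brute-force enumeration on ~200
random small maps; the Monte Carlo test's type-I error is measured on 500
null datasets of 20 areas × 50 at risk with 999 replicates each; parameter
recovery runs 20 independent surveys of 3 000 respondents on a 30-area
lattice with 8 000-iteration chains; DIC discrimination uses 20 replicates
each of strong-field and no-field data at n = 1 200; interval calibration
uses 500 simple random samples of 500 at p = 0.3.  These sizes are scaled to
finish in minutes while leaving Monte Carlo error comfortably inside the
asserted bands.

## Known limitations

- The ICAR re-centering step is exactly likelihood-preserving only on
  connected graphs; with islands the deficit folded into β₀ is the
  area-weighted mean across components (the usual case in practice is a
  connected county graph).
- Single-site updates mix slowly when τ_s is very large (a nearly constant
  field); block updates are not implemented.
- The scan offers circular windows and the Bernoulli model only — no
  elliptic windows, space–time scanning, or covariate adjustment.
- Survey estimation covers single-stage-weight designs with Taylor
  variances; replicate-weight methods (jackknife/BRR) are out of scope.
- DIC is reported as defined above; alternatives (WAIC, cross-validation)
  are not provided.
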