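# spatialprev

Spatial analysis of survey-measured binary outcomes: design-weighted
prevalence estimation, Besag–York–Mollié-type hierarchical spatial logistic
modelling with DIC model selection and posterior risk mapping, and Bernoulli
spatial scan cluster detection — together with a DHS-like synthetic survey
generator so the whole workflow can be validated against known ground truth.

It is written for epidemiologists and biostatisticians who analyse
complex-survey data (e.g. Demographic and Health Surveys) over an
administrative geography — the motivating application is mapping the risk of
a traditional practice such as female genital mutilation/cutting across
counties — and who need the three standard layers of such an analysis in one
place: descriptive design-based estimates, model-based disease mapping, and
cluster detection.

## The models

**Hierarchical spatial logistic regression.** For respondent *i* in area
*a(i)*,

    Y_i ~ Bernoulli(p_i),      logit p_i = β₀ + x_i'β + f_s(a_i) + f_u(a_i)

where *x_i* holds dummy-coded categorical covariates, *f_u* is an
unstructured iid Gaussian area effect with precision τ_u, and *f_s* is a
spatially structured effect with an intrinsic CAR (Gaussian Markov random
field) prior on the area adjacency graph with precision τ_s:
log-kernel ((m−k)/2)·log τ_s − (τ_s/2)·Σ_{i~j}(f_s,i − f_s,j)², identified
by a per-component sum-to-zero constraint.  Four nested variants are
distinguished: Model 1 (no area effects), Model 2 (f_u only), Model 3
(f_s only), Model 4 (both).  Fixed effects carry near-flat Gaussian priors
(precision τ_β, default 10⁻⁴) and the precisions vague Gamma(0.5, 0.0005)
priors.  Posteriors come from a Metropolis-within-Gibbs sampler (conjugate
Gamma draws for τ_s, τ_u) and models are compared by the deviance
information criterion, DIC = D̄ + pD with pD = D̄ − D(θ̄); smaller is better.

**Bernoulli spatial scan statistic.** Areas are aggregated to case/control
counts (c_i of n_i).  Circular windows grow around every area centroid in
great-circle-distance order (capped at 50% of the population at risk), and
each window *z* is scored by the log-likelihood ratio

    LLR(z) = c·ln(c/n) + (n−c)·ln((n−c)/n)
           + (C−c)·ln((C−c)/(N−n)) + (N−n−C+c)·ln(1−(C−c)/(N−n))
           − C·ln(C/N) − (N−C)·ln((N−C)/N)

one-sided for high- or low-rate clusters.  Significance comes from Monte
Carlo randomization conditioning on C and the n_i; secondary clusters are
reported greedily without geographic overlap.

**Design-weighted estimation.** Prevalence uses the ratio estimator with
stratified between-PSU Taylor-linearized variance and logit-scale 95% CIs;
cross-tabulations use the second-order (Satterthwaite) Rao–Scott corrected
Pearson statistic on an F reference; a media-exposure index is the first
principal component of ordinal media items, cut at weighted tertiles.

## Worked example

`examples/` contains one short script per capability.
`python examples/04_hierarchical_model.py` simulates a 20-area survey with a
genuine spatial field, fits all four models and maps the best one:

```
Model 1: DIC =  1774.30   pD =   5.0
Model 2: DIC =  1602.47   pD =  22.3
Model 3: DIC =  1601.17   pD =  20.5
Model 4: DIC =  1600.98   pD =  20.5

best model by DIC: Model 4

adjusted odds ratios (posterior median, 95% CrI):
  age_group=15-24         1.00 (1.00-1.00) (ref)
  age_group=25-34         1.55 (1.16-2.18)
  age_group=35-49         2.64 (1.91-3.59)
  education=none          1.00 (1.00-1.00) (ref)
  education=primary       0.69 (0.49-0.94)
  education=secondary+    0.44 (0.31-0.65)

posterior prevalence, highest area a01: mean 0.65 (95% CrI 0.55-0.75)
```

The DIC drop of ~170 from Model 1 to the spatial models shows the simulated
area heterogeneity being absorbed by the random effects (here Models 2–4 are
within 2 DIC units of one another, i.e. effectively tied); the credible
intervals bracket the generating odds ratios (1.65, 2.72, 0.67, 0.41); and
the mapped area a01 is one the generator actually made high-risk.

The same workflow runs from the shell via a YAML config:

```sh
spatialprev all --config examples/demo.yaml --outdir run --seed 7
```

writing descriptive tables, per-model fit directories, a DIC comparison, a
posterior prevalence choropleth (CSV + GeoJSON) and a cluster report, plus a
manifest pinning every seed and assumption.

## File formats

- **Centroids**: CSV with header `id,lon,lat`, coordinates in decimal
  degrees (see `examples/data/centroids.csv`).
- **Adjacency**: GAL-dialect text — a header line with the area count, then
  per area a line `id n_neighbors` followed by a line of neighbour ids
  (`examples/data/adjacency.gal`).  One-directional entries are symmetrized
  with a warning; unknown ids are rejected.
- **Survey records**: CSV with columns `outcome, weight, stratum_id,
  psu_id, area_id` plus one column per categorical factor.
- **Area case data**: CSV with header `id,cases,total`; round-trips through
  `AreaCaseData.read_csv`/`to_csv`.
- **Maps and clusters**: GeoJSON FeatureCollections with point geometries
  at area centroids and the mapped values as feature properties.

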