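# Methods

## Problem and model

The package estimates *family-planning coverage* — the proportion of women
using a modern contraceptive method among women who actually need
contraception (sexually active, fecund, not pregnant, wanting to avoid
pregnancy) — and maps its geographic variation from a two-stage cluster
survey with household GPS.

The analysis unit for the spatial model is the enumeration-area (EA)
cluster. Conditional on the true prevalence P(x_i) at cluster location x_i,
the number of users Y_i among the n_i women in need sampled there is

    Y_i | P(x_i) ~ Binomial(n_i, P(x_i)),
    logit P(x_i) = beta0 + D_i beta + S(x_i),

where D is a dummy-coded design matrix of categorical covariates (age group,
education, marital status, religion, wealth, parity, media exposure, ever
pregnant, partner discussion, partner attitude, fertility intention,
residence, distance-to-facility category, region) and S(.) is a zero-mean
Gaussian process with variance sigma^2 and Matérn correlation

    rho(u; phi, kappa) = 2^(1-kappa)/Gamma(kappa) (u/phi)^kappa K_kappa(u/phi),

with u the great-circle distance in km.  Individual covariates are preserved
exactly by expanding each cluster into covariate-pattern cells: women in the
same EA with the same covariate pattern form one binomial row sharing the
cluster's S(x_i).

## Inference: dense-GP Laplace with a hyperparameter grid

With at most a few hundred clusters, dense covariance algebra is exact and
fast, so no sparse-precision (SPDE/mesh) machinery is used.  Writing
theta1 = log sigma^2 and theta2 = log phi:

1. A regular grid (default 15 x 15 over +/- 3 hyperprior sds) is laid over
   (theta1, theta2).  At each node the joint mode of (beta, S) is found by
   Newton's method; the binomial-logit log likelihood plus Gaussian priors is
   strictly concave, so convergence is guaranteed.  Stopping uses the
   gradient sup-norm (1e-6) or the affine-invariant Newton decrement
   (1e-9) — the latter matters at near-degenerate nodes where the precision
   matrix is enormous and an absolute gradient tolerance is unattainable in
   floating point.
2. Each node receives a Laplace-approximate log marginal likelihood
   (log target at the mode plus half the log-determinant correction), and
   nodes are weighted by marginal likelihood x hyperprior, pruned to within
   10 log-units of the best node.
3. **Importance-sampling correction.** The Gaussian at the joint mode is
   known to misplace the marginal mean of strongly skewed coefficients
   (this is why nested-Laplace software does not stop at the joint-mode
   Gaussian).  At every retained node with weight > 0.02 we draw 2,000
   samples from the node Gaussian and reweight them by the exact log joint
   (self-normalised importance sampling; the correction is skipped if the
   effective sample size falls below 50).  Coefficient and latent-field
   summaries are then computed from the pooled weighted draws mixed with the
   Gaussian summaries of minor nodes.  In replicate experiments this removes
   a mode-vs-mean bias of ~0.1 on the strongest coefficient (partner
   discussion, true log-odds ~3) and restores nominal interval coverage.
4. Posterior quantiles are read off the resulting grid mixture by
   root-finding on its CDF.

Priors (configurable): beta ~ N(0, 10^2) i.i.d. (including the intercept);
theta1, theta2 ~ N(0, 2^2).  kappa is fixed at 1 by default — the common 2-D
choice — because it is only weakly identified from a single realization;
it can be set to any positive value.

An independent MCMC sampler over the same posterior (elliptical slice
updates for S, componentwise adaptive random-walk Metropolis for beta, joint
random walk for theta) serves as a cross-check; the suite requires
coefficient agreement within 3 combined posterior sds on a shared fixture.

## Prediction

Prevalence at unsampled locations is obtained by composing posterior draws:
sample a hyperparameter node by weight, a (beta, S) draw from that node
(importance-corrected where available), krige S to each lattice point by
exact GP conditioning (pointwise conditional mean and variance), and push
beta0 + d0' beta + S* through the inverse logit, where d0 is a fixed
covariate profile (default: the weighted-mean design row).  Means and
2.5%/97.5% quantiles over 2,000 draws give the surface and its credible
band; the same draws yield the spatial-field mean and sd surfaces.

## Survey estimation

Coverage estimates are Hájek ratios sum(w y)/sum(w).  Variance uses Taylor
linearisation with the EA as primary sampling unit and urban/rural residence
as stratum under the with-replacement approximation; intervals are Wald on
the logit scale, with one-sided exact (Clopper-Pearson) bounds for
degenerate all-0/all-1 groups.  Distance summaries are unweighted by default
(they describe the sample; a weighted option exists).  Disparity contrasts
between extreme subgroups report both the absolute gap in percentage points
and the relative gap 100 (p1 - p2)/p2, each with a seeded EA-level bootstrap
interval (1,000 resamples); both scales are reported because a
percentage-point reading of a relative gap is a recurrent source of
ambiguity in coverage-gap tables.

## Spatial autocorrelation

Global Moran's I is computed on per-EA use proportions with row-standardised
k = 8 nearest-neighbour weights (great-circle distance, index tie-break);
k-NN is robust to the very uneven EA spacing of a national sample, and a
distance-band alternative is provided.  Inference is reported both from the
normality-assumption moments (z score) and from a seeded permutation null,
p = (1 + #{|I_perm| >= |I_obs|})/(n_perm + 1).

## Synthetic-data generator

The generator emulates the 2019 PMA Ethiopia design, which the analysis
assumes but whose microdata are restricted:

- **Design**: 265 EAs uniform in a national bounding box (lon 33-48,
  lat 3.4-14.9), 30.4% urban stratum; a census PPS size measure M_i and a
  noisily re-listed household count H_i give two-stage inverse-inclusion
  weights w_i = 1/(pi1_i pi2_i) with 35 households selected per EA — weights
  are constant within EA and vary across EAs.  Women in need per EA are
  Poisson(16.6), minimum 1.
- **Covariates**: drawn independently per woman from the survey-weighted
  category marginals (e.g. 44.6% never attended school, 83.1% married,
  41.6% discussed family planning with their partner).  Joint dependence
  between factors is not modelled — only marginals are published.
- **Geography**: a stylised 4x3 grid of named regions over the bounding
  box; zones split each region cell.  Households jitter ~1 km around the EA
  centroid.
- **Facilities**: 799 SDPs, 68.5% public.  One serving facility per EA at a
  lognormal displacement (median ~0.9 km, sigma_log = 1.55, truncated at
  60 km) calibrated so the realized nearest-distance profile matches the
  survey (~70% within 2 km, ~4-5% beyond 6 km, mean ~2 km); remaining
  facilities concentrate near urban EAs.
- **Outcomes**: the logistic model above with the published posterior-mean
  log-odds as true effects, a Matérn(kappa = 1) field with sigma^2 = 1 and
  phi = 100 km, and intercept beta0 = -1.19, calibrated once by simulation
  so the default realization's weighted coverage sits near the survey's 44%
  (realization-to-realization sd is ~3-4 points, dominated by the latent
  field).  The Somali-region effect (-2.5) is a choice: the source tables
  show essentially zero uptake there, which leaves the effect unidentified.
  Users' methods are drawn from the renormalised national method mix
  (injectable .561, implant .321, pill .061, other .057).

What the generator does **not** emulate: GPS displacement of released
cluster coordinates, nonresponse, within-household correlation, covariate
dependence across factors, and spatially varying covariate prevalence.
Passing tests therefore demonstrate correctness of the estimators under the
assumed design, not robustness to those real-data complications.

## Numerical choices

- Great-circle (haversine) distances on the IUGG mean radius everywhere;
  distance categories are right-closed at 2 and 6 km.
- Covariance matrices get a 1e-8 sigma^2 diagonal jitter, escalated tenfold
  to at most 1e-4 sigma^2 before failing with the smallest eigenvalue.
- Printed-table comparisons use decimal half-up rounding.
- Nearest-SDP ties break on the smallest facility id; k-NN ties on index.
- All randomness flows from explicit integer seeds; pipeline artifacts are
  byte-identical across reruns with the same seed and configuration.

## Problem sizes in the test and acceptance suites

Parameter recovery runs 25 replicates at the full study scale (265 EAs,
~16 women per EA).  Prediction calibration uses 20 replicates of 100
clusters x 100 lattice nodes with an intercept-only model.  The
Laplace-MCMC agreement fixture uses 40 clusters and two factors with 6,000
MCMC iterations.  The end-to-end determinism check runs a reduced pipeline
(50 EAs, 7x7 hyperparameter grid).  These sizes keep the full suite
comfortably within a desk-scale run while exercising every code path at the
study's own scale where it matters.

## Known limitations

- The reported theta1/theta2 are on this package's own log-variance /
  log-scale parameterisation; published spatial-effect summaries from
  SPDE-based software use a different internal parameterisation and are not
  directly comparable.
- Moran's I depends on the unstated weights specification of any published
  value; the k = 8 default is a reasonable convention, not a reproduction.
- With ~4-5% of women beyond 6 km of a facility, the far-distance
  coefficient is the least identified of the strong effects (posterior sd
  ~0.3-0.45) and is partially confounded with the latent field.
- Fixed-truth frequentist coverage of 95% credible intervals is slightly
  below nominal for the single strongest coefficient (partner discussion,
  true log-odds ~3): likelihood-based point estimates of such a large
  logistic effect carry a small away-from-zero finite-sample bias (visible
  even in an oracle fit given the true field), and the estimator's sampling
  spread modestly exceeds the posterior sd.  The recovery suite therefore
  observes ~0.85-0.90 interval coverage for that coefficient while the
  other strong effects sit at 0.92-0.96; this reflects the estimand's
  scale, not an approximation defect (the MCMC cross-check gives the same
  posterior sd to within 2%).
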