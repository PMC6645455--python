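# Methods

## The model

All analyses are phylogenetic generalized least squares (PGLS)
regressions of a (log-scale) trait on a set of predictors:

    y = X b + e,    e ~ N(0, sigma^2 * V(lambda)),

where V is the Brownian-motion variance–covariance matrix implied by the
phylogeny — V[i, j] is the branch length shared from the root to the most
recent common ancestor of species i and j, V[i, i] the root-to-tip
distance — and Pagel's lambda in [0, 1] multiplies V's off-diagonal,
interpolating between phylogenetic independence (lambda = 0, ordinary
least squares when the diagonal is constant) and full Brownian structure
(lambda = 1). Trees need not be ultrametric; nothing assumes a constant
diagonal except where noted.

Estimation is by Cholesky whitening: with V(lambda) = L L', ordinary
least squares on (L^-1 y, L^-1 X). No explicit matrix inverse is formed.
lambda is estimated by maximum likelihood, profiling over a 101-point
grid on [0, 1] refined by bounded scalar minimization in the winning
grid cell; the optimum is therefore always within 0.01 of the grid
argmax, and a test asserts it dominates every grid point. The profile is
evaluated through a one-time eigendecomposition of the
diagonal-standardized V (every V(lambda) = lambda V + (1 − lambda) D is
simultaneously diagonalizable after D^{-1/2} scaling), which makes each
lambda evaluation an O(n p^2) weighted least squares; the final fit at
the chosen lambda goes back through the Cholesky path, and the two
routes are pinned together to 1e-8 in tests.

When the profile is flat to within 1e-8 across the grid (lambda
unidentifiable — a star phylogeny is the canonical case) or any
evaluation fails numerically, lambda falls back to 1 and the fit is
flagged `lambda_fixed`. The fallback is deliberately the error path:
comparative analyses in practice fix lambda = 1 when the optimizer
misbehaves near the boundary, and the flag preserves that information
per model.

### Likelihood and reporting conventions

* The likelihood is full ML (not REML). AIC comparisons across models
  with different fixed-effect sets are only valid under ML, and the
  whole point of the multiverse is AIC-comparability.
* `sigma2` and the log-likelihood use the ML variance RSS_w / n.
  Standard errors, t and p-values (two-sided, df = n − p with p the
  number of terms including the intercept) and prediction intervals use
  the unbiased variance RSS_w / (n − p). This is the only pairing under
  which the degenerate limits are exact: at lambda = 0 on a
  constant-diagonal V the fit reproduces OLS coefficients, SEs and
  p-values to 1e-8, and the prediction interval under V = I equals the
  OLS closed form.
* AIC = −2 loglik + 2k with k = (#terms) + 1 for sigma^2 + 1 for lambda
  *only when lambda was estimated*. A fallback-fixed lambda is not a
  free parameter. The rule is uniform across a multiverse so rankings
  are comparable.
* R^2 is the squared Pearson correlation between fitted and observed
  values. It is a crude, report-friendly summary — not a likelihood
  pseudo-R^2 — and is undefined (an error, not 0) when the fitted values
  are constant.
* Prediction for a new observation ignores its phylogenetic covariance
  with the modeled species (its position on the tree is unknown); the
  residual-variance term uses the mean tip variance of the
  lambda-transformed V. Predictions are on the fitted (log) scale;
  back-transforming the bounds by exponentiation yields the familiar,
  strongly asymmetric intervals.

## The multiverse

For one outcome, k candidate predictors and a mandatory covariate (body
mass — female weight in the primate design), all 2^k − 1 non-empty
candidate subsets are fitted, each with the covariate included. With
k = 6 this is 63 models per outcome, each candidate appearing in 32.
Enumeration order is by subset size then lexicographic in the given
candidate order, and that order is the tie-breaker everywhere (AIC ties
additionally prefer fewer predictors); the module contains no RNG.

One species set is shared by all models: the complete cases over the
outcome, the covariate and *all* candidates, intersected with the tree.
Per-model complete cases would make AIC values incomparable and N
heterogeneous; the shared-set rule keeps a single N for every table.

Stability summaries per candidate: the count of models in which it is
non-significant (strictly p > alpha, alpha = 0.05 by default; p = alpha
counts as significant), and the minimum and maximum p-value with the
focal-predictor sets of the attaining models. Concomitant listings
exclude the focal predictor itself and the mandatory covariate. No
multiple-testing correction is applied anywhere — the multiverse is a
description of analyst-choice sensitivity, not a family of confirmatory
tests; alpha inflation across 63 models is real and is the caveat the
stability tables exist to expose.

Per-model failures (e.g. a rank-deficient design) are recorded as
failure records, excluded from AIC ranking, and do not abort the run.

## Diagnostics

* **VIF**: 1/(1 − R^2_j) from regressing predictor j on the others with
  intercept. Exact collinearity reports an infinite VIF and names the
  aliased set. "PGLS VIF" is the same computation on the whitened design
  L^-1 X at the model's lambda — it equals the plain VIF exactly when V
  is the identity or the tree is a star. Values above 10 are flagged as
  conventionally "worrying" but gate nothing.
* **Partial R^2** of a term: (RSS_reduced − RSS_full)/RSS_reduced in the
  whitened space at the full model's lambda. Partial R^2 values do not
  sum to the model R^2 under collinearity, and a test asserts they do
  not.
* **Posterior slope correlations**: slopes are weakly identified when
  predictors share information, and their joint posterior shows it —
  when b1 rises b2 must fall. Rather than MCMC, draws come from the
  exact Normal–Inverse-Gamma conjugate posterior under a flat prior on
  (b, log sigma^2) at fixed lambda: sigma^2 | y ~ InvGamma((n−p)/2,
  RSS_w/2), b | sigma^2 ~ N(b_hat, sigma^2 (X'V^-1X)^-1). This is a
  deliberate methodological substitution for a hierarchical MCMC
  treatment of the same diagnostic target: it has no mixing pathology,
  is reproducible by seed, and for two standardized predictors with
  correlation r yields slope correlation ≈ −r (the closed-form
  signature of the trade-off). It does not include varying intercepts
  or informative priors.

## Data pooling and transforms

Multiple literature sources are pooled per (species, variable) cell by
weighted averaging, sum(w x)/sum(w) over sources reporting the cell.
The weights behind published "weighted averages" are generally
unrecoverable; the default here is equal weights, with per-source
scalars or per-cell weight frames accepted and recorded in provenance.
Pooling is invariant to source order and to splitting a source into
half-weight copies.

Transforms: natural log for sizes, counts and durations (natural rather
than base-10 — either is defensible for published slope magnitudes, and
the choice is recorded per column); asin(sqrt(p)) for dietary
proportions, with percent columns divided by 100 first (the arcsine is
undefined otherwise, which forces the scaling). Transform state is
tracked per column and a second application is an error, not a silent
double-log. Life span is derived as maximum recorded age minus age at
female sexual maturity, and a non-positive difference is an error that
flags a data problem.

Complete-case extraction returns the rows with no missing value on the
analysis variables that are also tips of the tree, prunes the tree to
match (path lengths preserved exactly; the pruned VCV equals the
corresponding submatrix of the full VCV), and reports every dropped
species with its reason.

## The synthetic generator

The generator emulates the structure of the empirical primate design
the package targets — roughly 40 species, a body-mass covariate that
dominates brain-size variation, six mutually correlated candidate
predictors, phylogenetically structured residuals — without reproducing
any real measurements.

* **Trees**: pure-birth (Yule), unit splitting rate, rescaled to unit
  root-to-tip depth (ultrametric by construction), tips labelled
  deterministically; bit-reproducible by seed.
* **Predictors**: matrix-normal, X = L Z R' with L L' = V(lambda_pred)
  and R R' the target trait correlation matrix. This is the simplest
  construction giving independent control of phylogenetic signal and
  cross-trait collinearity; empirical correlations converge to the
  target as n grows.
* **Responses**: y = X beta + e with e ~ N(0, sigma^2 V(lambda_resid)).
  Composed with the fitting pipeline this is an unbiased-estimation
  test bed, and null coefficients yield uniform p-values.

The frozen "paper-like" fixture (default seed 20190722) has 40 tips,
predictor names matching the primate variables (female weight, female
and male group size, female sexual maturity, life span, innovation,
fruit), mean absolute pairwise predictor correlation ≈ 0.3–0.5, a
covariate-only PGLS R^2 of ≈ 0.95 for the "total_brain" outcome
(body size explains most of the variation, as in the real system), and
two small non-zero predictor effects. Verified at generation and pinned
by tests: the fixture regenerates byte-identically from its seed, and
its 63-model multiverse contains predictors whose p-range spans 0.05 —
the instability phenomenon the package exists to expose.

What the fixture does *not* emulate: measurement error and intraspecific
variation, missing data patterns, non-ultrametric trees, non-Gaussian
traits, and any real covariance values (the empirical correlation
magnitudes are not public in usable form; the fixture's are stand-ins).
Passing tests therefore demonstrate correctness of the machinery and
the qualitative collinearity-instability effect, not agreement with any
particular empirical dataset.

## Calibration results and problem sizes

The validation suite and `scripts/acceptance.py` use these problem
sizes, chosen to make Monte-Carlo error small relative to the claims:
200 random GLS instances (n ≤ 12) for the estimator-oracle check; 50
simulated datasets (60 tips) for optimizer-vs-grid agreement; 500
replicates at 200 tips for CI coverage and null-p uniformity, at
lambda ∈ {0, 0.5, 1} with lambda estimated each time; 4 matched seeds ×
3 correlation levels (40 tips, 15 models each) for the
instability-vs-collinearity curve; 10^4 draws for the posterior checks.

Measured with these sizes: slope-coefficient CI coverage 92–96%
(within the 90–98 band), null p-values KS-uniform, and the mean
per-predictor p-range width increasing strictly with predictor
correlation (≈ 0.43 → 0.57 → 0.63 for r = 0 → 0.5 → 0.95 at the
default seed).

## Known limitations

* The intercept's CI undercovers slightly (down to ≈ 90% at n = 200)
  when lambda is estimated: reported SEs condition on the plug-in
  lambda-hat, and the root-state variance is the quantity most
  sensitive to lambda. Slope inference is essentially unaffected; the
  coverage claims above are about the slope coefficients, and the
  intercept's coverage is reported separately by the acceptance script.
* ML-based SEs carry the usual finite-sample optimism relative to REML;
  REML is deliberately off the AIC path and not implemented.
* The lambda upper bound is 1: values above 1 can destroy positive
  semidefiniteness. Data generated by processes with stronger-than-
  Brownian covariance will pile estimates at the boundary.
* p-values, AIC and R^2 are reported at full precision; any "<0.000"
  style truncation is purely a markdown-rendering convention.
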