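# Methods

## The model

`expofactor` treats a wide panel of environmental exposure items as
indicators of a latent **general exposome factor** g plus a small
number of **orthogonal specific factors** s_1..s_S (household,
neighborhood, day-to-day experiences, and so on in the motivating
application). Each observed item follows

    x_i* = lambda_g,i * g + lambda_s,i * s_a(i) + sqrt(psi_i) * e_i,

with all factors and errors independent standard normal and
psi_i = 1 - lambda_g,i^2 - lambda_s,i^2. Continuous items are observed
directly; ordinal and binary items are discretised versions of x_i* cut
at fixed thresholds tau (the latent-normal / item-factor-analysis
convention). Under this measurement model the population correlation
of two items is lambda_g,i lambda_g,j (+ lambda_s,i lambda_s,j if they
share a specific factor), which is what the polychoric/polyserial
estimators target.

## Mixed-type correlations

Correlations are estimated pairwise with the estimator matched to the
declared measurement levels: Pearson (continuous-continuous),
polyserial (continuous-ordinal), polychoric (ordinal-ordinal). Both
latent-correlation estimators are **two-step ML**: thresholds are fixed
at the inverse-normal of observed cumulative margins, then the single
correlation is maximised against the bivariate-normal likelihood
(Brent's method on (-0.999, 0.999), |x| tolerance 1e-7). Two-step
rather than joint ML is the standard choice: nearly identical
estimates, much cheaper, and the thresholds are consistent by
construction.

Bivariate-normal rectangle probabilities use a fixed 64-node
Gauss-Legendre rule on Owen's single integral after the arcsine
substitution; the rule is deterministic and accurate to ~1e-14
(validated against an independent CDF implementation in the tests), so
correlation estimates are bit-reproducible across runs.

Pairwise deletion is used for all correlation estimation; association
models later use listwise deletion. Pairwise-deleted matrices can be
indefinite, so the pooled matrix is smoothed by eigenvalue clipping
(floor 1e-6) with rescaling to unit diagonal, iterated to a fixed
point; PSD input passes through unchanged.

Degenerate inputs: empty categories are collapsed (with a warning)
before threshold estimation; perfect association returns the boundary
estimate +/-0.999 with a warning; a pair with fewer than 10 complete
observations is an error naming the columns.

## Redundancy reduction

Real exposure panels contain near-duplicates (the same construct
reported twice) and dead items. The reduction loop makes that cleanup
explicit and auditable instead of curatorial: each pass estimates the
mixed correlation matrix, runs an oblimin EFA at the parallel-analysis
factor count, then (a) collapses connected groups of variables with
pairwise |r| >= `r_merge` (default 0.90) to a single representative —
the member with the highest communality, preserving measurement level —
or optionally to a mean-of-standardized composite for all-continuous
groups, and (b) drops variables with communality below
`min_communality` (default 0.10). The loop stops when a pass takes no
action or after `max_iterations` (default 9) passes. Every removal is
recorded with its reason and value; the surviving count is
non-increasing by construction.

## EFA, retention, and iterated target rotation

Extraction is minres/ULS: for fixed uniquenesses the loadings are the
scaled top-k eigenvectors of R - diag(psi), and psi minimises the sum
of squared residual eigenvalues (L-BFGS-B with an analytic gradient,
psi bounded in [0.005, 1]; hitting the lower bound is reported as a
Heywood cap at communality 0.995). The factor count defaults to Horn's
parallel analysis (95th percentile of 100 seeded normal resamples); a
configured k can override it.

Rotation uses Jennrich's gradient-projection algorithm for two oblique
criteria: direct oblimin with gamma = 0 (direct quartimin — the
standard default; nothing in the application dictated another gamma)
and partially specified target rotation, which penalises only loadings
at positions the target pins to zero. **ITR** starts from the oblimin
pattern, builds a target whose zeros are the positions with |lambda| <
c (c = 0.30, the same cutoff used for pattern bolding and pruning),
target-rotates, rebuilds the target, and repeats until the zero
pattern is unchanged. A detected pattern cycle returns the
lowest-criterion member with a warning. Because positions above the
cutoff stay free, ITR can recover true cross-loadings that quartimin
shrinks toward zero; on planted complex structure its per-column
Tucker congruence with the truth is at least oblimin's.

Outputs are canonicalised (columns ordered by sum of squared loadings,
leading sign positive, Phi permuted to match) so solutions are unique.

## Bifactor model

The EFA pattern configures a quasi-confirmatory bifactor model: each
item is assigned to the specific factor of its largest absolute pattern
loading (ties to the lower factor index, logged; items with no loading
>= c are excluded, logged). Estimation minimises the unweighted
least-squares discrepancy

    F = 1/2 * sum_{i<j} (r_ij - sigma_ij(theta))^2

over the general and specific loadings, with Sigma(theta) =
lambda_g lambda_g' + sum_s lambda_s lambda_s' + diag(psi). Five seeded
starts guard against local minima; signs are canonicalised (mean
loading per factor nonnegative); psi is reported as
1 - lambda_g^2 - lambda_s^2 floored at 0. An item may also be declared
general-only (its specific loading fixed absent), which nests the
one-factor model exactly.

This ULS-on-polychoric estimator replaces the mean-and-variance-
adjusted weighted least squares used by commercial SEM software. The
population solution is identical and no asymptotic covariance matrix of
the polychoric estimates is needed; the cost is that the T = (N-1)*F
statistic is not chi-square calibrated, so CFI/RMSEA here are
internally consistent approximations rather than values comparable to
WLSMV output. SRMR (root mean squared off-diagonal residual) is
estimator-agnostic. Fit indices follow the usual formulas: RMSEA =
sqrt(max(T - df, 0) / (df (N-1))), CFI = 1 - max(T - df, 0) /
max(T_b - df_b, T - df, 0) against the independence baseline. Family
clustering affects standard errors, not these point estimates; a
cluster-resampling bootstrap can be layered on by resampling family
ids.

Pruning iteratively removes items with |lambda_s| < c and refits,
never reducing a specific factor below 3 items (identification floor;
blocked removals warn). Bifactor indices use the closed forms
ECV = sum(lambda_g^2) / (sum(lambda_g^2) + sum(lambda_s^2)),
omega_H = (sum lambda_g)^2 / ((sum lambda_g)^2 + sum_s (sum_{i in s}
lambda_s,i)^2 + sum psi), omega_HS analogously per subfactor (NaN when
a subfactor has no specific variance), and factor determinacy
FD_f = sqrt([L' R^-1 L]_ff) with L the full orthogonal loading block.

## Factor scores

Items are standardised first — continuous columns z-scored, ordinal
columns replaced by conditional-normal scores E[Z | tau_{j-1} < Z <=
tau_j], keeping scoring on the same latent-normal scale as the
polychoric model. Scores are the regression method F = X R^-1 L,
restandardised per column, with rows containing any missing item
dropped and counted. Determinacy (FD) describes exactly these scores:
at large n the empirical correlation between the estimated and true
general factor matches FD within sampling error.

Regression scores of an orthogonal model are themselves correlated
(implied covariance L' R^-1 L). When the scores feed a downstream
model as orthogonal predictors, `orthogonalize=True` symmetrically
whitens them (ZCA), making their sample correlations exactly zero while
staying as close as possible to the regression scores; their
correlation with the true factors is then slightly below FD. The
pipeline uses whitened scores for the association stage and raw
regression scores for determinacy reporting.

## Association models

All continuous variables are z-scored before OLS so coefficients are
standardized betas; adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-p-1). The
delta-R^2 report fits the covariate-only and full models on the
identical listwise-complete rows and returns both adjusted R^2 values,
their difference and ratio. Logistic models are ML fits with Wald 95%
CIs on the odds-ratio scale; detected separation is an error
suggesting a penalized fit. Demographic contrasts use the Welch
(unequal-variance) t-test — the conservative default when equal
variances are unverifiable — with classic pooled-SD Cohen's d and
Bonferroni adjustment for m = 7 comparisons. The sensitivity model is
a linear mixed model with a site random intercept and family variance
component nested in site, fitted by REML (Powell optimiser, which
converges reliably where L-BFGS stalls on boundary-adjacent variance
components).

## Synthetic cohorts: what they emulate, and what not

The generator plants the exact structure the analysis assumes:
orthogonal standard-normal latent factors; family clustering as an
exchangeable shared component (within-family correlation =
`icc_family`, default 0.30 — siblings share much of their household
environment but not all of it); mixed measurement levels (continuous,
binary, 3-5 category ordinal at fixed thresholds; category counts are
configurable, not estimated); MCAR missingness (default 2%); and
outcome models with planted effects. The planted effect sizes are the
headline values reported for the motivating cohort analysis, reused as
generative truth: standardized beta 0.285 of the general factor (and
0.518 for the day-to-day subfactor) on the continuous psychopathology
score with full-model adjusted R^2 0.382 against ~0.04 for
demographics alone; obesity OR 1.41 and advanced-puberty OR 1.30 per
SD of the general factor at prevalences 16.7% and 6.5%; income and
parental-education contrasts of d = 1.40 and 1.16 on the general
factor, induced by coupling the median-split group indicators to g at
analytically derived strengths. Direct (conditional-on-exposome)
covariate effects are set near zero, which is what centres the
covariate-only adjusted R^2 at ~0.04.

Passing recovery tests on these cohorts shows the estimators are
correct under the assumed model. It does not show robustness to what
real cohorts add: non-normal latent distributions, MNAR missingness,
measurement non-invariance across sites or demographic groups,
genuinely nominal items, or model misfit (which is why synthetic fit
indices are near-perfect while real-data CFI/RMSEA are not).

## Numerical and design choices

- Problem sizes in the test suite and acceptance script (36-40 items,
  n = 3000-20000, 1 general + 4-6 specific factors) are chosen as the
  smallest sizes at which the planted-recovery tolerances are
  comfortably met; they scale the real panel down by roughly a factor
  of 2-3 in items.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline rounds numeric CSV output
  to 6 decimals so artifact hashes are stable across reruns.
- Optimiser tolerances: Brent |x| <= 1e-7 (latent correlations),
  L-BFGS-B ftol 1e-15 / analytic gradients (minres, bifactor ULS), GPA
  gradient norm < 1e-6 (rotations).
- Ties in bifactor assignment go to the lower factor index and are
  logged; ITR pattern cycles return the lowest-criterion member.
- Known limitations: no asymptotic covariance of the polychoric
  matrix (hence no WLS weight matrix and no chi-square-calibrated fit
  statistics); no modification indices or correlated residuals; no
  multiple imputation (deletion policies only); the redundancy loop is
  a rule-based stand-in for what is, in real applications, partly
  expert judgement.
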