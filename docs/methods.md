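# Methods

## The model

The bi-factor integration model (BFIM) assumes each of p continuous items
measures one common target trait plus the shared variance of its own
questionnaire:

    y_ij = nu_i + lambda_ig * T_j + lambda_ik(i) * eta_jk(i) + eps_ij,

with T and the K specific factors eta_k mutually orthogonal and standard
normal a priori, and eps_ij ~ N(0, theta_i).  Identification follows the
standardized-factor convention: factor means 0, specific variances fixed at
1, free loadings everywhere.  When structural covariates x (here SNP and
sex) are present, the trait is regressed on them,

    T_j = gamma' x_j + zeta_j,   zeta_j ~ N(0, psi_zeta),

and the scale is fixed by **deriving** the disturbance variance,
psi_zeta = 1 - gamma' S_x gamma, where S_x is the sample covariance of the
covariates.  The marginal trait variance is therefore exactly 1 and gamma
is on the same standardized scale as the generating coefficients, which is
what makes "relative bias against 0.0447" a meaningful quantity.  The
conditional distribution used by the likelihood is

    y_o | x  ~  N( nu_o + lambda_g,o (gamma'x),
                   psi_zeta lambda_g,o lambda_g,o' + Lambda_s,o Lambda_s,o'
                   + Theta_o ),

restricted to the observed item set o.  The implied *marginal* covariance
(integrating over x) is Lambda I Lambda' + Theta — the form
`implied_covariance` returns by default and the form used for factor
scoring.  A small set of residual covariances can be freed for item pairs
known a priori to be near-duplicates across questionnaires (the "bridge"
pair below); each enters Sigma only in patterns where both items are
observed.

## Estimation

With continuous indicators the observed-data likelihood is closed-form
Gaussian; no numeric integration is needed for this model class.  Rows are
grouped by missingness pattern, and within each pattern the log-likelihood
and its analytic gradient are evaluated from cached cross-moments
(y'y, x'x, x'y and the column sums), so one evaluation costs O(k^3) per
pattern regardless of sample size.  Optimization is L-BFGS-B (residual
variances bounded below at 1e-4 against Heywood collapse) followed by
damped Newton steps on the free parameters using the central-difference
Hessian of the analytic gradient; a fit is declared converged when the
per-observation projected gradient falls below 1e-5 (parameters resting on
the Heywood floor with an outward-pointing gradient are projected out, as
in any active-set criterion), with one jittered restart on failure.
Standard errors are observed-information (inverse of the free-parameter
block of that Hessian); floor-bound residual variances get no SE.  The
sign indeterminacy is resolved by making each factor's loading sum
positive, with gamma flipping together with the general factor.

Starting values: item means for nu, 0.5 for all loadings, half the
observed item variances for theta, 0 for gamma and freed covariances.

The saturated model (for fit measures) is estimated by EM for an
unstructured mean and covariance under MAR to an absolute log-likelihood
tolerance of 1e-8; the independence baseline factors by item and is solved
in closed form.  RMSEA, CFI and TLI use their standard chi-square
definitions with chi2 = 2(ll_sat - ll_model).

Regression factor scores are the conditional means
Psi Lambda_o' Sigma_o^{-1}(y_o - nu_o) with Psi = I on the marginal
moments; subjects with no observed items receive the prior mean 0 and are
flagged.  Regression scores shrink: Var(T-hat) <= 1.

## The synthetic-data generator

The generator emulates the study conditions of the simulation this package
reproduces: two cohorts with disjoint 4-item questionnaires, a complete
reference panel, a biallelic SNP (MAF 0.5, additive 0/1/2 coding under
Hardy-Weinberg) explaining 0.1% of trait variance (gamma_snp = 0.0447), a
binary sex covariate explaining 20% (gamma_sex = 0.8944), and disturbance
variance 0.799 completing the unit trait variance.  Items 4 and 5 — the
last item of questionnaire 1 and the first of questionnaire 2 — form a
"bridge" pair with residual correlation 0.6, mimicking similarly worded
items across instruments.  Four generating models:

1. **Ideal measurement.** Every item: 25.5% general, 34.5% specific, 40%
   residual variance (loadings sqrt(0.255), sqrt(0.345), equal across
   items).
2. **Reliability differences.** Questionnaire 2's communality drops to
   45%, split between general and specific factors in the same 25.5:34.5
   ratio as model 1 (the only split that preserves model 1's structure);
   residual variance 55%.
3. **Mean/variance shift.** Model 2 plus questionnaire-2 specific factor
   ~ N(1, 3).  Item marginal variances exceed 1 by design; the fitted
   model's unit-variance, zero-mean specific factors absorb the shift into
   nu and rescaled specific loadings.
4. **Higher-order trait.** T feeds two questionnaire factors F_k = b T +
   u_k (b = 0.51, Var u = 0.74), items load sqrt(0.6) on their
   questionnaire factor, and items {1, 2, 5, 6} receive an extra direct
   effect of T of 0.2; residual variances are solved so every item has
   unit marginal variance.  b is calibrated so the mean squared effective
   trait loading equals model 1's 25.5%, keeping complete-data association
   power comparable across generating models.  Note that a higher-order
   model with partial direct effects is still covariance-equivalent to an
   unconstrained bi-factor model — the "misspecification" consists of
   violated proportionality constraints, so it is deliberately mild.

Sample-size conditions: N1 = 5000/5000/400, N2 = 2500/2500/400,
N3 = 7500/7500/400, N4 = 2500/7500/400, N5 = 4500/4500/1000
(cohort1/cohort2/reference).  Null (type-I error) datasets are fresh draws
with gamma_snp = 0 and the disturbance raised to 0.8 to keep unit trait
variance.  The no-reference-panel variant drops the panel, reallocates its
subjects (split evenly between equal-size cohorts; all to the smaller
cohort when unbalanced) and merges the bridge pair into one shared column
observed in both cohorts, the real-world practice of recoding items with
similar face validity as the same item.

What the generator does **not** emulate: categorical or skewed item
response scales, rater or age effects on measurement parameters, linkage
disequilibrium or multiple variants, population stratification, and family
clustering.  Passing tests therefore demonstrate correctness of the
machinery and reproduction of the simulated operating characteristics —
not performance on real consortium data, where categorical items and
cluster-robust standard errors would be required.

## Analysis arms and their estimands

All arms include sex alongside the SNP in the association step, and all
Wald 95% intervals are estimate ± 1.96 SE.

- **Complete-data SEM** (benchmark): BFIM + structural regression on the
  pre-masking data.
- **Mega-analysis**: the same model on the missing-by-design data.
- **Factor-score meta-analysis**: BFIM without the SNP fitted to the
  combined data, regression scores for T, per-study OLS (cohort 1,
  cohort 2, panel), fixed-effects inverse-variance pooling.  Two modelling
  choices matter here.  (i) The fitted model frees the bridge pair's
  residual covariance: leaving the 0.6 residual correlation unmodelled
  tilts the general factor toward the bridge pair and attenuates the SNP
  coefficient by roughly half, which is incompatible with the published
  near-zero mega-analysis bias; the analyst knows this pair a priori — the
  no-panel design uses exactly that knowledge to merge them.  (ii) The
  factor-score model keeps sex as a structural covariate (the variant is
  excluded): without any anchor the general/specific split is identified
  only by the small panel and the fit wanders along a near-flat ridge,
  putting per-study scores on different scales and collapsing the pooled
  z-statistic.
- **Sum-score meta-analysis**: per-subject mean of available items,
  otherwise as above.
- **Multiple imputation**: chained equations over the 8 items (5 sweeps,
  m imputed datasets, default 50; the study driver uses m = 20 at desk
  scale), each item imputed from the other 7 plus SNP and sex by type-1
  predictive mean matching — Bayesian regression with a
  normal-inverse-gamma posterior draw, each missing cell borrowing the
  observed value of one of k = 5 donors with nearest predicted mean —
  then the item sum regressed on SNP + sex over all subjects and pooled by
  Rubin's rules with Barnard-Rubin degrees of freedom.

Bias and coverage are judged against each arm's own population estimand:
gamma itself for the latent-trait arms; for the manifest-score arms the
closed-form population coefficient of that arm's outcome on the SNP (mean
of available items, true-parameter regression score, or complete item
sum), pooled across studies with population inverse-variance weights.
A sum-score coefficient, for instance, targets (mean general loading) ×
gamma, not gamma — comparing it to gamma would report a mechanical −50%
"bias" that says nothing about the method.

## Monte-Carlo study

Replications are independent work units seeded by
SeedSequence(base, model, condition, replication, null-flag, stream), so
results are bit-reproducible and independent of execution order and of
which arms are requested.  Non-converged replications (optimizer failure,
non-positive-definite information) are excluded from the metrics and
reported as a convergence rate, flagged unreliable below 50%.  Default
problem sizes are desk scale — 200 replications per cell (binomial SE
about 0.035 at power 0.5), with the imputation arm at 100 replications and
m = 20 — and a `--reps 1000` run of the study CLI reproduces the original
scale.  Type-I error uses fresh null draws, never refits of the same data.

## Numerical choices and edge cases

- Residual-variance floor 1e-4; a boundary solution (Heywood case) is a
  legitimate converged fit when the projected gradient vanishes.
- Scale boundary gamma' S_x gamma >= 1 is handled by a smooth likelihood
  barrier; `unpack_parameters` raises `InfeasibleScaleError` outside it.
- Freed residual covariances are unbounded; an indefinite Sigma simply
  returns -inf and the line search backs off.
- Rows with zero observed items are dropped from the likelihood with a
  warning and scored at the prior mean.
- The EM saturated fit raises on non-convergence, making fit indices
  unavailable rather than silently wrong.

## Known limitations

Continuous-indicator Gaussian likelihood only (no categorical links, no
robust/clustered standard errors, no MNLFA-style covariate-moderated
measurement); fixed-effects pooling only (no random-effects
meta-analysis); one variant at a time.  The no-panel configuration is
weakly identified by construction; its fits may sit on ridges or fail, and
the package reports rather than hides this.
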