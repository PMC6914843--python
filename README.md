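# bfim — bi-factor integration modelling for multi-cohort phenotype harmonization

Genetic consortia routinely measure the *same* behavioural phenotype with
*different* questionnaires: cohort A rates aggression with one item set,
cohort B with another, and a per-cohort sum score throws the measurement
differences into the meta-analysis as phenotypic heterogeneity.  `bfim`
implements model-based harmonization with a **bi-factor integration model
(BFIM)**: every item loads on one general factor *T* (the target trait,
common to all cohorts) and on exactly one questionnaire-specific factor
that absorbs instrument-specific shared variance.  All factors are
orthogonal and standard normal,

```
y_ij = nu_i + lambda_ig T_j + lambda_ik eta_jk + eps_ij        (measurement)
T_j  = gamma_snp SNP_j + gamma_sex sex_j + zeta_j              (structural)
```

Concatenating cohorts produces missing-by-design data (each cohort observes
only its own items); a small phenotypic **reference panel** with complete
data on all questionnaires links the item sets.  Estimation is
full-information maximum likelihood (FIML) over missingness patterns —
valid under MAR, which holds exactly here because missingness is determined
by cohort membership.  The trait scale is standardized by deriving the
structural disturbance variance, `psi_zeta = 1 - gamma' S_x gamma`, so the
marginal trait variance is 1 and SNP coefficients are comparable across
analysis strategies.

The package is aimed at statistical geneticists and psychometricians
planning consortium analyses.  It provides, besides the model itself, the
full comparison battery used to quantify what harmonization buys:

- **BFIM mega-analysis** — one joint SEM on the pooled subject-level data,
  Wald test on `gamma_snp`;
- **factor-score meta-analysis** — measurement-only BFIM, regression factor
  scores, per-study OLS, fixed-effects inverse-variance pooling;
- **sum-score meta-analysis** — mean of available items per subject,
  per-study OLS, the same pooling;
- **multiple imputation** — chained-equations predictive mean matching of
  the items, imputed-sum-score mega-regression, Rubin's rules;
- a synthetic-data generator for four generating models (ideal measurement,
  unequal reliability, shifted specific factor, higher-order trait) and a
  Monte-Carlo study driver reporting power, type-I error, relative bias and
  95% coverage per condition.

## Worked example

Simulate two cohorts of 2,500 with disjoint 4-item questionnaires plus a
400-subject reference panel (a SNP explaining 0.1% and sex explaining 20%
of trait variance), then fit the BFIM mega-analysis by FIML:

```python
import numpy as np
from bfim import build_generating_model, generate_dataset, SAMPLE_SIZE_CONDITIONS
from bfim.estimate import BiFactorModel

spec = build_generating_model(1)
data = generate_dataset(spec, SAMPLE_SIZE_CONDITIONS["N2"], np.random.default_rng(7))
model = BiFactorModel.from_dataframe(
    data,
    groups={"Q1": ["y1", "y2", "y3", "y4"], "Q2": ["y5", "y6", "y7", "y8"]},
    covariates=["snp", "sex"],
    residual_cov_pairs=[("y4", "y5")],   # known similarly-worded bridge pair
)
res = model.fit()
print(res.summary())
```

```
Bi-Factor Integration Model (FIML)
==========================================================
N subjects: 5400    patterns: 3
log-likelihood: -27529.600    converged: True
iterations: 45    |grad|_inf: 1.04e-07
----------------------------------------------------------
item           nu  lambda_g  lambda_s    theta
y1         0.0256    0.5063    0.5793   0.3923
y2        -0.0040    0.4772    0.6004   0.3886
...
y8         0.0483    0.4899    0.6298   0.4138
----------------------------------------------------------
covariate        gamma        se       z         p
snp             0.0067    0.0323    0.21  8.35e-01
sex             0.9152    0.0753   12.16  5.14e-34
psi_zeta (derived): 0.7905
==========================================================
```

The general loadings recover the generating value `sqrt(0.255) = 0.505`,
sex recovers `0.8944`, and the SNP estimate (truth `0.0447`) is
indistinguishable from zero in this single replicate — at n = 5,400 the
SNP test has roughly 35% power, which is exactly why the package ships a
replication driver.  `res.factor_scores()` returns per-subject regression
scores of the general and specific factors for downstream association
testing, and `res.fit_measures()` (measurement-only fits) reports
chi-square, RMSEA, CFI and TLI against the FIML saturated model.

A command-line interface mirrors the library
(`bfim simulate | fit | score | assoc | meta | impute | study`); e.g.

```bash
bfim simulate --model 1 --sizes N1 --seed 11 -o data.csv
bfim study --models 1 --sizes N1 --reps 200 --seed 3 -o out/
```

writes `table2.csv` (power and type-I error per arm), `table3.csv` (bias
and coverage), per-replication records and a run log.

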