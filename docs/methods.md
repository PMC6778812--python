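# Methods

## The prediction problem

Plant-breeding programs phenotype J candidate lines for L correlated traits
across I environments, but field trials are rarely complete: many
(line, environment) cells are never planted. Genomic selection fills those
cells by regressing phenotypes on genome-wide marker similarity. This
package implements a two-stage *multi-output regressor stacking* approach
in a Bayesian setting (BMORS) and the univariate GBLUP baseline it stacks
on, together with the cross-validation protocol and accuracy metrics used
to compare them.

## Stage 1 — univariate GBLUP with G×E

For one trait, the response of line j in environment i is modelled as

    y_ij = E_i + g_j + gE_ij + e_ij

* `E_i` — fixed environment effect. Its "flat" prior is implemented
  literally as N(0, 1e10), not as an improper prior, so every full
  conditional stays proper. The intercept is absorbed into the environment
  effects (the environment incidence spans the constant column).
* `g = (g_1..g_J) ~ N(0, sigma2_g * G)` — genomic line effects.
  `G = WW'/p` is the genomic relationship matrix from the J×p dosage
  matrix W (markers coded 0/1/2) with p the marker count.
* `gE ~ N(0, sigma2_ge * I_I ⊗ G)` — genotype-by-environment interaction:
  independent across environments, kernel-correlated across lines.
* `e_ij ~ N(0, sigma2_e)` iid residuals.

### Marker QC and the kernel

Markers are filtered in the fixed order missingness → minor allele
frequency → heterozygosity. All three statistics are computed on the
original calls (the filters are independent passes); a marker failing
several rules is logged under the first. The MAF rule is *inclusive*
(`MAF <= threshold` removes), matching common breeding-pipeline
conventions; defaults are 0.8 maximum missingness, 0.05 MAF, and a
disabled heterozygosity filter (enable at 0.10 for genotyping-by-sequencing
panels with residual heterozygosity). Remaining gaps are filled by
column-mean imputation before the kernel is formed.

Marker columns are **centered by default** before `WW'/p`: the raw 0/1/2
coding would make G depend on which allele is counted, while centering
yields the standard VanRaden-style kernel. The literal uncentered product
is available via `center=False`. The divisor is exactly p — not the
`2 Σ p_k(1−p_k)` of VanRaden's method 1 — so `sigma2_g` is calibrated to
this kernel's own scale. G must be PSD up to a relative tolerance of 1e−8;
when an inverse is needed (variance updates), the eigen-pseudoinverse with
eigenvalue floor `1e-8 * lambda_max` is used, which also pins together the
effects of genomically identical lines.

### Priors and their parameterisation

Variance components carry scaled inverse chi-square priors in the
`S / chi2_v` parameterisation (density ∝ (s²)^−(v/2+1) exp(−S/2s²); mode
S/(v+2), mean S/(v−2)). The scales are derived from the training-set
phenotypic variance:

| component  | v | S                       | prior mode        |
|------------|---|-------------------------|-------------------|
| sigma2_g   | 5 | Var(y) × 0.50 × (v+2)   | 0.50 × Var(y)     |
| sigma2_ge  | 5 | Var(y) × 0.25 × (v+2)   | 0.25 × Var(y)     |
| sigma2_e   | 5 | Var(y) × 0.25 × (v+2)   | 0.25 × Var(y)     |

The `(v+2)` factor is exactly what makes S the prior *mode* times (v+2) in
this parameterisation — rival conventions differ by factors of v, which is
why the parameterisation is fixed and tested. The G×E scale (R² = 0.25) is
this package's choice: it partitions Var(y) as 0.5 genomic + 0.25 G×E +
0.25 error, so the three prior modes sum to the phenotypic variance. A
response with (near-)zero training variance gets a floor of 1e−8 on Var(y)
so the prior scales stay positive; the fit then collapses to environment
means, which is the sensible degenerate answer.

### Gibbs sampler

All full conditionals are conjugate; there is no Metropolis step or
tuning. Per iteration: environment effects (diagonal Gaussian), the g
block drawn *jointly* from its J-dimensional Gaussian full conditional
(Cholesky of `Ginv/sigma2_g + diag(n_j)/sigma2_e`), the gE block drawn as
I independent J-dimensional Gaussians (its prior precision and incidence
crossproduct are both block-diagonal over environments), then the three
variances via `(S + q)/chi2_{v+k}` with quadratic forms `g'Ginv g`,
`Σ_i gE_i'Ginv gE_i` and the residual sum of squares. Lines with no
training records are sampled in every iteration through their kernel
correlation with trained lines, so "never-tested" material is predicted
with no extra machinery. Default chain: 10,000 iterations, 5,000 burn-in,
thinning 5 — deliberately conservative; the experiments below use shorter
chains (stated per experiment) because posterior-*mean* predictions
stabilise long before full posterior summaries do.

Predictions are posterior means of the linear predictor
`E_i + g_j + gE_ij` — for training cells too (fitted values, not observed
values).

## Stage 2 — stacking with a Bayesian ridge

Each trait's stage-1 model predicts all N = J×I cells. Per trait, the
prediction vector is standardised — subtract its mean, divide by its
sample SD (n−1) — over **all N cells**, training and testing together.
The per-cell subscripts sometimes attached to these scaling constants in
the stacking literature cannot be read literally (a per-cell
standardisation of a single number is identically zero); the constants are
per-trait scalars. Scaling over all N cells uses no test *labels*, only
stage-1 predictions, so no leakage occurs, and the meta-features seen at
training and prediction time are on one common scale.

The meta-model for target trait l on the training cells is

    y_ij = b0 + beta_1 Zhat_1ij + ... + beta_L Zhat_Lij + e_ij

with `beta_k ~ N(0, sigma2_beta)` shared across coefficients,
`sigma2_beta ~ ScaledInvChi2(5, Var(y)×0.5×7)`,
`sigma2_e ~ ScaledInvChi2(5, Var(y)×0.25×7)`, and an intercept with the
same N(0, 1e10) prior as environment effects. The intercept is included
even though the textbook stacking regression omits it: the meta-features
are centered but the response is not, so without it the model is
mis-located. Coefficients are unconstrained (non-negativity restrictions
were considered and rejected upstream of this design), and the original
marker features are deliberately *not* added to stage 2. Stage-1
training-set covariates are in-sample fitted values — no inner
cross-validation — matching the design this package reimplements; all
trait fits within a stage share one chain seed, so duplicated traits give
bit-identical meta-features.

With L = 1 the meta-model is an affine map of the single stage-1
prediction, so BMORS and plain GBLUP test predictions correlate at exactly
±1 — a structural identity the tests assert.

## Cross-validation and metrics

The random CV mimics incomplete trials: per partition,
`m = round(p_testing × N)` lines are drawn — with replacement if J < m,
without otherwise (`round` is banker's rounding; the convention is stated
because N×p_testing is often a half-integer) — and one environment is
picked uniformly per drawn line. The drawn cells form the testing set;
duplicates collapse, so with-replacement testing sets can be smaller than
m. Every model sees byte-identical partitions. Defaults: p_testing 0.2,
10 partitions.

* **APC** — Pearson correlation of observed vs predicted test values,
  averaged over partitions (sample SD across partitions reported). A
  zero-variance vector makes the correlation undefined; it is reported
  missing and excluded from the average rather than coerced to 0, which
  would silently reward constant predictors. Metrics pool test cells
  across environments per trait by default (one row per model × trait);
  `by_env` adds per-environment rows.
* **MAAPE** — mean of `arctan(|(y−ŷ)/y|)` in radians, in [0, π/2]. The
  y=0, ŷ≠0 term contributes π/2 (the arctan limit); y=0, ŷ=0 contributes
  0, making the metric total.

## Synthetic data

The generator draws from the matrix-variate multi-trait model
`Y = Xβ + Z1 b1 + Z2 b2 + E` with `b1 ~ MN(0, G, Σt)`,
`b2 ~ MN(0, ΣE ⊗ G, Σt)` and iid residual rows `N(0, Re)` — the natural
fully multivariate generative model for correlated traits with G×E, even
though no multivariate *fitter* ships here: it gives exact control of the
cross-trait genetic correlation that determines whether stacking can help.
Kronecker square roots (`chol(ΣE)⊗chol(G)`) are applied blockwise, so the
IJ×IJ covariance is never formed; factorisations add a relative jitter of
1e−8×λmax.

Markers are independent biallelic loci, dosage ~ Binomial(2, f) with f
uniform on the MAF range — no linkage disequilibrium, population
structure, selection, or spatial field effects. Consequently the synthetic
experiments validate the *estimator and pipeline mechanics*, not
performance on structured real populations: kernels from real panels are
rougher and trait architectures sparser than anything this generator
produces.

The default scenario is a mid-size trial — J=300 lines, I=3 environments,
L=3 traits, p=1000 markers, genetic correlation 0.5, variance scales
(1.0, 0.5, 0.5) for genomic/G×E/residual — chosen as typical of a single
breeding-cycle yield-trial analysis and small enough that a full 10-fold
random CV runs in minutes on one CPU.

## Experiment sizing

* The conjugate-sampler oracle (frozen variances vs the direct
  mixed-model-equations solve, J=8, I=2) uses 20,000 retained draws,
  agreement within 0.02.
* Variance-component recovery runs at J=300, I=3 over 5 seeds with
  2,000-iteration chains (1,000 burn-in, thin 2); posterior means fall
  within 30% of truth on average.
* The stacking-vs-univariate comparison runs the full CV (10 partitions)
  at J=300 with 1,000-iteration chains, which is sufficient because only
  posterior-mean predictions enter APC/MAAPE. With genetic correlation
  0.9, per-trait APC of BMORS stays within 0.05 of (or above) the
  univariate baseline; with independent traits the two are
  indistinguishable to the same 0.05 — stacking neither helps nor hurts
  when there is nothing to borrow.
* `scripts/acceptance.py` re-runs the same three experiments at J=150
  (comparison) and J=200 (recovery, 3 seeds) to keep a full from-scratch
  reproduction under a few minutes.

## Known limitations

* Stage 1 is GBLUP only; the API keeps the stage-1 fits as a list
  precisely so other learners could slot in, but none ship.
* No REML/frequentist path, no multi-kernel (pedigree + genomic) models,
  no per-environment residual variances, no leave-one-environment-out CV.
* The fully multivariate Bayesian multi-trait multi-environment model is
  used only as a data generator, never fitted.
* Phenotypes are assumed to be field-design-adjusted means (BLUEs);
  stage-0 experimental-design adjustment is upstream of this package.
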