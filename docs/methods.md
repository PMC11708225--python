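# Methods

## The statistical problem

`mageit` tests whether the variants in a gene region interact with a scalar
environmental exposure to influence a phenotype. The unit of inference is a
region (a gene), not a single variant: individual interaction effects —
especially for rare variants — are far too small to detect one at a time,
but a variance-component formulation can aggregate them. The package
implements two marginal interaction tests:

* **MAGEIT_RAN** — genetic main effects modelled as *random*;
* **MAGEIT_FIX** — genetic main effects treated as *fixed* nuisance
  covariates and projected out.

## Model

For subject *k* with phenotype `y_k`, covariates `X_k` (m columns),
exposure `E_k`, and dosages `G_k = (G_k1..G_kp)`:

    y = a0*1 + X a1 + a2 E + G beta + S gamma + eps

where `S` has rows `S_k = E_k * G_k`, `gamma ~ N(0, (sigma^2/p) W2^2)`,
`eps ~ N(0, tau^2 I)`, and, in the random-main formulation,
`beta ~ N(0, (omega^2/p) W1^2)`. `W1`, `W2` are diagonal beta-density
weights of minor-allele frequency (below), concentrating signal on rarer
variants. The null hypothesis of no interaction is `H0: sigma^2 = 0`.

Left-multiplying by the projector `M = I - b(b'b)^{-1}b'` with
`b = [1, X, E]` (random-main) or `b = [1, X, E, G]` (fixed-main) removes
the fixed effects, leaving `y* ~ N(0, omega^2 G* + sigma^2 S* + tau^2 M)`
with the weighted linear kernels

    G* = (M G W1)(M G W1)'/p,      S* = (M S W2)(M S W2)'/p.

## Estimation and test statistic

Variance components are estimated by method of moments (MQS): matching
`y*' A y*` to its expectation for probe matrices `A in {G*, S*, M}` yields
a linear "trace system" solved in closed form; `sigma2_hat` is the test
statistic. In fixed-main mode the analogous 2x2 system gives

    sigma2_hat = [d y*'S*y* - tr(S*) y*'y*] / [d tr(S*S*) - tr(S*)^2],

with `d` the residual degrees of freedom. Method-of-moments estimates may
legitimately be negative; the statistic is never floored.

Under H0, `sigma2_hat = y*' H y*` is a quadratic form in a Gaussian vector
with covariance `Sigma_0 = omega0^2 G* + tau0^2 M` (random-main) or
`tau0^2 M` (fixed-main), hence distributed as a mixture
`sum_i lambda_i chi2_1` with `lambda_i` the eigenvalues of
`Sigma_0^{1/2} H Sigma_0^{1/2}`.

**Null components.** For MAGEIT_FIX, `tau0^2 = y*'y*/d`. For MAGEIT_RAN
the null components `(omega0^2, tau0^2)` come from the natural
2-component restriction of the moment system (probe matrices `G*` and
`M`), floored at zero — the null covariance must be PSD for its square
root — with the raw signed solutions kept in diagnostics and a flag
recording any flooring. An alternative construction that reuses the
unrestricted 3-component estimates (`null_from_estimates`) is exposed for
comparison but is not the default: in calibration runs it is
anti-conservative (empirical size ~0.017 at nominal 0.01, n = 5,000)
because the unrestricted components are negatively coupled to the
statistic's own fluctuation, whereas the restricted refit reproduces the
reference calibration (~0.010 at nominal 0.01, n = 5,000). Both
estimators are unbiased for `(omega^2, tau^2)` under H0.

**Statistic flooring.** Only the null components are floored. The
statistic itself can be negative and its signed mixture (the fixed-main
`H` has a negative identity coefficient, so the bulk eigenvalue is
negative) accommodates that.

## Spectrum without n x n matrices

`G*`, `S*`, `M` all act inside the rank-(n-q) projection subspace, so the
mixture spectrum has three exact blocks: 0 with multiplicity q; the bulk
value `c * tau0^2` (c = identity coefficient of H) with multiplicity
`n - q - r`; and r eigenvalues of an r x r symmetric problem, where r is
the rank of `F = [Gfac, Sfac]`. The reduced problem is assembled purely
from the Gram matrix `F'F` (one O(n p^2) product, cached and shared with
the trace system), so a genome scan never materialises an n x n matrix. A
dense O(n^3) path exists solely as an independent oracle in the tests;
fast and dense spectra agree to 1e-6 on fixtures up to n = 2000.

## Tail probabilities

`P(sum lambda_i chi2_1 > q)` is computed by numerical inversion of the
characteristic function (the classic quadratic-form algorithm with
adaptive truncation bounds and an optional Gaussian convergence factor),
implemented natively over distinct eigenvalues with multiplicities — the
high-multiplicity bulk costs the same as one eigenvalue. Target accuracy
is 1e-6 with a 10^6-evaluation cap. On integration fault, or when the
tail lies beyond the achievable accuracy, the moment-matching
(skewness/kurtosis) noncentral-chi-square surrogate is used instead and
flagged (`method = "liu_tang_zhang"`); for left-skewed mixtures the
reflected form is matched so the surrogate keeps its canonical right skew.
The two routes agree within 10% relative for p in [1e-4, 0.5] on random
spectra. Reported p-values are clamped to [1e-300, 1]. Eigenvalues below
1e-10 of the spectral radius are treated as numerical zeros; negative
eigenvalues are retained.

## Binary phenotypes

A binary outcome is the indicator that a latent unit-variance Gaussian
liability crosses zero. The exact likelihood is an n-dimensional integral;
instead the nuisance effects are fitted by probit regression of y on
`[1, X, E]`, genetic terms are assumed small enough to ignore in the
posterior, and each subject's liability is replaced by its posterior mean
(truncated-normal mean, evaluated through log-scale Mills ratios so
|mu| ~ 8 stays finite). The continuous pipeline then runs on these
posterior means unchanged. The identifiability constraint (variance
components summing to one) is applied as a joint rescaling of statistic
and spectrum; the test is scale-invariant, so the constraint is
presentational and verified not to move p-values beyond 1e-10 relative.
Case-control ascertainment is not corrected for — the approximation is
applied directly to the quota-sampled data, which is why the binary tests
run slightly conservative.

## Synthetic data generator

The simulation module emulates the study design the method was calibrated
under, with synthetic genotypes in place of the controlled-access cohort
data:

* **Genotypes.** Target MAFs uniform on (0.05, 0.5) for common and
  (0.005, 0.05) for rare variants; dosages Binomial(2, MAF), independent
  across variants. Gene profiles fix the size and common fraction
  (200 variants / 19% common, and 296 / 36%, matching the two template
  genes; a 2-common + 8-rare set for null studies). An optional
  Gaussian-copula AR(1) mode (default rho 0.5 when enabled) adds linkage
  disequilibrium; the default is independent so the null is exact.
* **Continuous trait.** `y = 0.05 X1 + 0.057 X2 + 0.64 E + genetic terms
  + N(0, 1.5^2)` with X1 ~ N(62.4, 11.5^2) (age-like), X2 ~
  Bernoulli(0.52) (sex-like), E ~ Bernoulli(0.5). Ten main-effect and ten
  interaction variants per replicate, sampled independently (sets may
  overlap), |beta| = 0.05 / 0.09 and |gamma| = 0.19 / {0.49, 0.59}
  (common / rare), signs set by the scenario's positive fractions with
  per-class balance.
* **Generator-side weights.** The causal coefficients are multiplied by
  the beta-density weights *rescaled to mean one over each causal set*
  (`trait_weight_norm="mean_one"`). Raw densities (up to ~25 at MAF 0.005)
  would let ten causal variants explain 70-80% of phenotypic variance;
  the mean-one form keeps the genetic share in the low single-digit
  percents — the regime the effect sizes above were designed for — while
  preserving the rare-upweighting shape. `"raw"` and `"none"` are
  reachable by config.
* **Binary trait.** Logistic model with intercept -6.2 (population
  prevalence ~= 0.08) and the same linear predictor; equal case/control
  quotas filled by block-wise oversampling. Only causal genotype columns
  are drawn for the oversampling pool — disease status is independent of
  the non-causal columns, which are therefore drawn after selection for
  the retained subjects only (an exact shortcut).
* **Analysis weights vs generator weights.** The analysis always computes
  `W1`, `W2` from the *sample* MAF of the data under test; the generator
  applies weights at the *generating* MAF. Same functional form, distinct
  objects.

What the generator does **not** emulate: real linkage-disequilibrium
structure (default off), population stratification, genotyping error or
missingness patterns, relatedness, or covariate-exposure confounding.
Passing calibration and power checks on this generator therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

## Study drivers and problem sizes

`type1_study` draws fresh null replicates (gamma = 0; ten causal
main-effect variants, all positive in scenario 1, half negative per class
in scenario 2) and reports rejection rates with binomial confidence
intervals; `power_study` does the same for non-null configs at a
configurable alpha (default 1e-4, 1,000 replicates at full scale). The
package's own calibration runs use 10^4 null replicates per cell — at the
reference n = 5,000 for the random-main test (whose size is
scale-dependent, see Limitations) and a reduced n = 1,000 for the
scale-stable fixed-main test — and 500 replicates per power scenario at
n = 5,000; sizes chosen so a full calibration pass completes on a single
CPU in tens of minutes while keeping the binomial SE at alpha = 0.01 near
1e-3.
Replicates are seeded per index (`SeedSequence(seed, spawn_key=(rep,))`),
so every study is reproducible from (config, seed) and any single
replicate can be regenerated in isolation.

## Numerical choices

* Projection via SVD with singular values below `1e-10 * s_max` treated as
  zero; rank deficiencies (collinear covariates, duplicated genotype
  columns in fixed-main mode) reduce the residual degrees of freedom and
  are flagged, rather than poisoning the solve.
* The trace system is solved directly (not by explicit inversion); a
  condition number above 1e12 raises an error naming the likely cause
  (near-constant environment).
* Monomorphic variants are excluded before weighting (the beta density is
  evaluated on (0, 0.5] only); subjects with any missing value are dropped
  (complete-case), not imputed.
* Genotype columns are flipped to minor-allele orientation at ingestion;
  the Hardy-Weinberg QC test runs only on hard-call columns and is skipped
  (flagged) for imputed dosages.

## Known limitations

* The random-main working model treats fixed simulated main effects as
  random; this is the method's own approximation and shows up as mild
  conservativeness, most visibly for binary traits. The effect grows as n
  shrinks: at n = 1,000 the random-main empirical size at nominal 0.01
  drops to ~0.007 (continuous) and ~0.004-0.006 (binary), while the
  fixed-main test is scale-stable. Calibration comparisons against the
  reference values are therefore made at n = 5,000 for the random-main
  test.
* No correction for case-control ascertainment in the liability pipeline.
* Rare-variant weights assume the supplied MAFs are minor-allele
  frequencies in (0, 0.5]; external MAFs are re-derived from dosages.
* The genomic-control adjustment assumes a 1-df chi-square transform of
  the p-values, which is a diagnostic convention rather than an exact
  null model for mixture statistics.
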