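# mageit

Set-based tests for **gene–environment interaction** (G×E) in genomic
regions that contain both rare and common variants.

Single-variant interaction scans are underpowered: per-variant G×E effects
are small, rare variants carry almost no information individually, and the
multiple-testing burden is severe. `mageit` instead tests a whole gene
region at once with a variance-component formulation. For phenotype `y`,
covariates `X`, a scalar exposure `E`, and a dosage matrix `G` of the `p`
variants in a region,

    y = α₀1 + Xα₁ + α₂E + Gβ + Sγ + ε,      Sₖ = Eₖ·Gₖ,

with interaction coefficients `γ ~ N(0, (σ²/p)W₂²)`. Testing
`H₀: γ = 0` reduces to testing the variance component `H₀: σ² = 0`.
Rare and common variants are weighted by a beta density of minor-allele
frequency — `Beta(MAF; 1, 25)` below the rare cutoff (0.05),
`c·Beta(MAF; 0.5, 0.5)` above it, continuous at the cutoff — so rarer
variants contribute more per allele.

Two tests are provided:

* **MAGEIT_RAN** — main effects `β` random, `β ~ N(0, (ω²/p)W₁²)`; a
  3-component method-of-moments (MQS) solve yields the statistic `σ̂²`.
* **MAGEIT_FIX** — main effects fixed and projected out with the other
  nuisance terms; a 2-component solve yields `σ̂²`.

Under H₀ the statistic is a (generally signed) mixture `Σλᵢχ²₁`; its tail
probability is computed by characteristic-function inversion with a
moment-matching fallback. Binary phenotypes are handled by a
liability-threshold approximation: a probit fit of the nuisance effects,
truncated-normal posterior means of the latent liability, then the
continuous pipeline on those posterior means. Continuous and binary
phenotypes, `ran` and `fix` modes all share one interface. See
`docs/methods.md` for the full model, estimation details and limitations.

## A worked example

Simulate a gene region with a planted interaction and test it:

```python
import numpy as np
from mageit import ScenarioConfig, A4GALT_LIKE, run_gxe_test
from mageit.simulate import simulate_continuous

cfg = ScenarioConfig(
    trait_type="continuous", profile=A4GALT_LIKE,   # 200 variants, 19% common
    causal_selection="two_common_eight_rare",
    sign_pattern=(1.0, 0.5),                        # mixed-sign interactions
    gamma_rare=0.49, n=5000,
)
data = simulate_continuous(cfg, np.random.default_rng(1))
for mode in ("ran", "fix"):
    res = run_gxe_test(data.inputs, mode=mode)
    print(mode, f"sigma2={res.statistic:.4f}", f"p={res.pvalue:.3g}", res.method)
```

```
ran sigma2=0.0154 p=1.93e-05 davies
fix sigma2=0.0094 p=0.0356 davies
```

`sigma2` is the estimated interaction variance component (the test
statistic) and `p` its mixture-of-χ² tail probability; `davies` records
that the characteristic-function inversion succeeded (the fallback would
report `liu_tang_zhang`). The random-main test is markedly more sensitive
here — the planted interaction has both positive and negative effects,
the regime where modelling main effects as random pays off.

The same engine drives calibration studies:

```python
from mageit.simulate import type1_study
study = type1_study(trait_type="continuous", scenario=1, method="ran",
                    n=1000, n_reps=10_000, alpha_levels=(0.01,), seed=0)
print(study.table[["alpha", "rate", "ci_low", "ci_high"]])
```

## Command line

```sh
mageit test  --vcf geno.vcf.gz --region 22:43088127-43117304:A4GALT \
             --pheno pheno.tsv --pheno-col sbp --covar-cols age,sex \
             --env-col alcohol --trait continuous --method ran
mageit scan  --bfile cohort --regions genes.bed --pheno pheno.tsv \
             --pheno-col htn --covar-cols age,sex --env-col alcohol \
             --trait binary --method ran --out scan.tsv
mageit simulate --study power --trait continuous --method ran --reps 500
```

`scan` applies the standard variant QC (call rate > 95%, MAF > 0.5%,
Hardy–Weinberg p > 1e-6 on hard calls), writes one row per gene
(χ² statistic, p-value, variant counts, flags), reports the
genomic-control inflation factor λ_GC, is resumable, and never aborts on a
per-gene failure. Genotypes come from indexed VCF (DS dosages preferred,
GT otherwise) or PLINK1 bed/bim/fam; regions from BED (0-based
half-open); phenotype/covariate tables are tab-delimited with a subject-ID
column.

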