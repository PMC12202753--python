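# pomskat

Set-based SNP association testing for **ordered categorical phenotypes**
under the proportional odds model.

Many disease phenotypes are ordinal — liver steatosis grades, or the four
anti-CCP antibody risk levels for rheumatoid arthritis — yet the standard
kernel association tests for SNP sets (SKAT and relatives) assume a
continuous or binary outcome.  `pomskat` fills that gap for geneticists
and biostatisticians who want to test a gene or region of `M` common
variants jointly against an ordinal outcome, adjusting for covariates.

## The test

For subject `i` with ordinal phenotype `y_i ∈ {0,…,J−1}`, covariates
`x_i` and dosages `g_i ∈ {0,1,2}^M`, the proportional odds model is

    logit P(y_i ≤ j) = ζ_j − x_i'γ − g_i'β ,   ζ_0 < … < ζ_{J−2}.

Instead of testing the `M` coefficients `β` one by one, they are modelled
as random with mean zero and variance `D(θ)`, and `H0: θ = 0` is tested
with the variance-component score statistic

    T = ½ (y − μ̂)' G̃ W G̃' (y − μ̂) ,

where `μ̂` is the fitted null mean of the integer-scored response, `G̃`
the dosages residualized on the covariates, and
`W = diag(BetaDensity(MAF_m; ½,½)²)` up-weights rarer SNPs.  Under `H0`,
`T ~ Σ_m λ_m χ²_1` with `λ` the eigenvalues of
`½ V^{1/2} G̃ W G̃' V^{1/2}` (`V` = null response variances); the p-value
comes from a Pearson Type III (shifted gamma) distribution matched to the
mixture's first three moments — exact for a single eigenvalue, and fast
enough to sweep thousands of gene sets.  A re-sampling p-value, and the
classical comparators (PCA-LRT, MinP, Bonferroni, joint QT), are included.
See `docs/methods.md` for the full account.

## Worked example

Simulate a 50-SNP region (AR(1) LD, ρ=0.5) with four causal SNPs
(β=0.2 each) and a 3-level phenotype for 2000 subjects, then test it:

```python
import numpy as np
from pomskat import SimulationConfig, pom_skat_test, simulate_dataset
from pomskat.simdata import maf_grid
from pomskat import comparators

cfg = SimulationConfig(n=2000, M=50, J=3, rho=0.5, maf=tuple(maf_grid(50)),
                       gamma=(0.5, 0.8), beta=(0.2,)*4, seed=42)
G, X, y, _ = simulate_dataset(cfg, replicate=0)

res = pom_skat_test(y, X, G)
print(f"T = {res.statistic_T:.1f}, T* = {res.T_star:.3f}, "
      f"xi = {res.xi:.3f}, p = {res.p_value:.4g}")
print(f"PCA-LRT p = {comparators.pca_lrt_test(y, X, G):.4g}")
ps = comparators.single_snp_pvalues(y, X, G)
print(f"Bonferroni p = {comparators.bonferroni_test(ps):.4g}")
```

prints

```
T = 4897.0, T* = 4.323, xi = 0.605, p = 0.0004781
PCA-LRT p = 4.967e-05
Bonferroni p = 0.006857
```

`T` is the raw quadratic-form score, `T*` its standardization by the null
mixture moments (4.3 null standard deviations above the null mean), `xi`
the mixture skewness that parameterizes the Pearson III reference, and
`p` the upper-tail probability: the region is clearly associated.  The
comparators agree; with weaker or sparser signals the set test typically
leads.

The same test runs from the shell on standard files (VCF, PLINK `.raw`,
or TSV dosages):

```sh
pomskat test --geno region.vcf --pheno pheno.tsv --pheno-col risk \
    --levels none,low,moderate,high --covars sex,age --out result.tsv
pomskat type1 --reps 500 --out table.tsv     # 18-scenario null sweep
```

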