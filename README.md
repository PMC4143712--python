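# lbltvc

Haplotype association testing for **longitudinal binary traits** with
**age-varying effects**: a logistic Bayesian LASSO whose haplotype
coefficients are cubic B-spline functions of age, estimated by MCMC with the
haplotype phase treated as a latent variable.

## Who this is for

Cohort studies (e.g. hypertension cohorts) often record a binary disease
status, smoking status and age at up to four examinations per unrelated
individual, together with unphased SNP genotypes. A haplotype's effect on
disease risk need not be constant over life: a variant may be neutral at 40
and strongly deleterious at 70. `lbltvc` estimates, for every haplotype in a
small block of SNPs (5 by default), a smooth per-copy odds-ratio curve
OR(t) over age with pointwise 95% credible intervals — including for **rare
haplotypes** (frequency below 5%), which shrinkage priors keep estimable
without pooling them away.

## The model

For individual *i* at examination *j* (age *t*), with latent diplotype
*Z\_i* and smoking status *X\_E(t)*:

```
logit P(Y_ij = 1) = β0 + Σ_h X_h β_h(t) + β_E X_E(t) + Σ_h β_{E,h} X_h X_E(t) + β_s X_s
β_h(t) = Σ_{l=1}^{L+4} β_hl B_l(t)
```

where *X\_h* counts copies of non-reference haplotype *h* in *Z\_i* and
*B\_l* are clamped cubic B-spline basis functions (interior knots (40, 60),
boundary knots (20, 100), hence 6 basis functions). The diplotype prior
allows departure from Hardy-Weinberg equilibrium via an inbreeding
coefficient *d*:

```
P(z_k / z_k') = d f_k + (1 − d) f_k²    (k = k')
              = 2 (1 − d) f_k f_k'      (k ≠ k')
```

Every regression coefficient except β0 gets a double-exponential (Laplace)
prior with a shared Gamma-distributed intensity — the Bayesian LASSO.
Sampling is Gibbs for the latent diplotypes (exact finite full conditionals
over each individual's phase-compatible set) and random-walk
Metropolis-Hastings for all continuous blocks, with proposal scales adapted
during burn-in. Since no public longitudinal genotype/phenotype resource
with these exact properties is freely available, the package ships a
synthetic-cohort generator with the matching structure (5 common + 2 rare
haplotypes, one causal haplotype of each class, smoking as a two-state
Markov process, haplotype×smoking interaction) plus drivers that estimate
type-I error and power over replicates.

## Worked example

```python
from lbltvc import (SimScenario, generate_dataset, AnalysisConfig,
                    MCMCSettings, fit_block)
from lbltvc.data_io import Cohort

geno, pheno, truth = generate_dataset(SimScenario(), seed=42)
cfg = AnalysisConfig(mcmc=MCMCSettings(iterations=4000, burn_in=1000,
                                       thinning=5, seed=1))
res = fit_block(Cohort(geno, pheno), cfg)
print(res.summary.significant_haplotypes())
c = res.summary.curves["GGTCC"]           # the generating causal haplotype
for a, m, l, u in zip(c.ages, c.median, c.lower, c.upper):
    print(f"{a:.0f}  OR={m:.2f}  [{l:.2f}, {u:.2f}]")
```

prints (abridged)

```
['AGGCG', 'GGTCC']
25  OR=0.15  [0.04, 0.33]
45  OR=0.61  [0.37, 0.90]
55  OR=1.35  [0.88, 1.99]
65  OR=2.19  [1.41, 3.43]
70  OR=2.51  [1.63, 3.83]
85  OR=2.59  [1.43, 4.58]
95  OR=1.85  [0.54, 9.17]
```

The causal haplotype GGTCC was generated with a per-copy odds ratio rising
from protective (~0.13 at age 25) through 1 near age 50 to ~2.5 at 65-70;
the posterior median curve recovers that profile, and the 95% band excludes
1 from age 60 on, so the haplotype is flagged significant. (`AGGCG` here is
a chance false positive of this single replicate; the replicate drivers
below quantify that rate.)

The same analysis is available from the shell:

```bash
lbltvc simulate --seed 42 --out sim/
lbltvc run -g sim/genotypes.tsv -p sim/phenotypes.tsv --seed 1 -o out/
lbltvc prescreen -g geno.tsv -p pheno.tsv -k 4 -o screen/   # block selection
lbltvc power --replicates 100 --seed 7 -o power/            # power study
```

`out/` contains `summary.tsv` (haplotype × age grid 25-95 × OR/L/U),
per-haplotype curve CSVs and plots, sampled-chain TSV, and a JSON manifest
with acceptance rates and convergence diagnostics.

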