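# Methods

## Model

For unrelated individual *i* with latent diplotype *Z_i* (an unordered pair
of haplotypes over a block of SNPs), observed at examinations
*j = 1..j_i ≤ 4*, disease status *Y_ij* is Bernoulli with

    logit P(Y_ij = 1) = β0 + Σ_h X_h β_h(t_ij) + β_E X_E(t_ij)
                        + Σ_h β_{E,h} X_h X_E(t_ij) + β_s X_s ,

where *X_h* ∈ {0,1,2} counts copies of non-reference haplotype *h* in
*Z_i*, *X_E(t)* is smoking status at the exam, *X_s* is sex, and each
haplotype's effect is expanded in a B-spline basis over age,
β_h(t) = Σ_l β_hl B_l(t). Disease statuses are conditionally independent
across exams given the exam-specific linear predictor; the longitudinal
correlation within an individual is induced by the shared latent diplotype
and shared covariates, not by an explicit residual process.

The diplotype prior is the inbreeding-coefficient model

    P(z_k/z_k') = d f_k + (1−d) f_k²   if k = k',
                  2 (1−d) f_k f_k'     otherwise,

with haplotype frequencies *f* and *d* capturing excess (d > 0) or deficit
(d < 0) of homozygosity; d = 0 is exactly Hardy-Weinberg equilibrium. The
probabilities are a proper distribution over unordered pairs iff
d ≥ −f_k/(1−f_k) for every k; the sampler enforces this bound (plus an
ε = 1e−8 margin) jointly whenever *f* or *d* moves.

The observed-data likelihood also factors over the smoking process and sex.
Those factors are given no parametric form here: they share no parameters
with the disease model or the frequency model, so they cancel from every
posterior ratio the sampler evaluates and are dropped as constants.

## Spline basis

The basis is the ordinary **clamped cubic B-spline** basis: interior knots
(40, 60), boundary knots (20, 100) repeated 4×, giving L + 4 = 6 basis
functions that are nonnegative and sum to 1 on [20, 100]. A *natural*
cubic-spline basis with the same knots would have only L + 2 free
functions; we use the ordinary basis because the model's coefficient count
per haplotype is L + 4, and no natural end-constraints are imposed. Ages
outside the boundary knots are rejected as invalid input. Evaluation uses
the standard Cox-de Boor recursion (via `scipy.interpolate.BSpline`); the
test suite checks it against an independent hand-written recursion and the
partition-of-unity identity at 1e−12.

## Phase handling and the haplotype universe

A genotype heterozygous at *h* sites is compatible with 2^(h−1) diplotypes.
The support of every individual is enumerated exactly and the latent *Z_i*
is Gibbs-sampled from its full conditional over that finite set.

The model's haplotype list starts from the phasing closure of the data (every
haplotype occurring in some compatible phasing of some individual). With a
5-SNP biallelic block this closure approaches all 32 strings while most of
them are phasing artifacts nobody actually carries, which would multiply
the coefficient count several-fold for no information. We therefore run the
HWE haplotype-frequency EM on the closure and drop haplotypes whose fitted
frequency falls below half a chromosome's worth, 0.5/(2n) — far below any
genuinely rare haplotype of interest (a few percent) — restoring any
haplotype an individual's support cannot do without, then re-run EM on the
reduced list. The EM fit (d = 0) supplies the MCMC starting frequencies, and
its most frequent haplotype is the reference absorbed into β0 (some
baseline must be fixed for identifiability). Haplotypes with frequency
below 0.05 are labelled rare in all reports.

## Priors and sampler

* Laplace(0, λ) on every penalized coefficient (all β_hl, β_E, each
  β_{E,h}, β_s) with one shared intensity λ ~ Gamma(a = 20, b = 20). The
  shared-intensity Bayesian-LASSO layout shrinks noise coefficients
  strongly while letting concentrated signals through, which is what makes
  rare-haplotype curves estimable.
* β0 ~ Normal(0, 10²), unpenalized.
* f ~ Dirichlet(1, …, 1). For *d* we use a flat indicator on its valid
  range given *f*: a normalized uniform on the moving range would make the
  prior density depend on *f* and couple the two blocks for no substantive
  reason.
* Updates per iteration: one Gibbs sweep over all latent diplotypes, then
  random-walk MH for β0, each haplotype's 6-coefficient spline block,
  β_E, the interaction vector, β_s, the frequency simplex (Gaussian walk in
  stick-breaking logits with the exact Jacobian), *d* (Gaussian walk
  reflected into its valid interval), and log λ (with the log-scale
  Jacobian). λ is conditionally conjugate but is MH-updated like every
  other continuous block for uniformity of the engine.
* Proposal scales adapt every 50 iterations during burn-in toward 35%
  acceptance and are frozen afterwards, so the retained draws come from a
  fixed-kernel chain. Acceptance rates, bulk ESS and a Geweke z-score are
  recorded in every run manifest.
* Initialization: β = 0, β0 at the logit of the observed prevalence,
  f from EM, d = 0, λ at its prior mean, each *Z_i* at its most probable
  supported diplotype.
* Default chain: 50 000 iterations, 10 000 burn-in, thinning 10. The tests
  and the acceptance script run 4 000-5 000 iterations with 1 000-4 000
  burn-in: on the simulated block (n = 250, ~7 haplotypes) posterior
  odds-ratio intervals from 4 000 and 12 000 iterations are
  indistinguishable, so the short chains are used wherever many replicate
  fits are needed.

Numerical notes: Bernoulli log-likelihoods use `logaddexp` (stable to
|η| ≈ 700); categorical draws in the Gibbs sweep use the Gumbel-argmax
trick on log-weights; proposals leaving a valid domain are auto-rejected;
anchor/p-value ties in the prescreen break toward the smaller bp position;
EM stops at relative log-likelihood change < 1e−8 or 500 iterations.

## Posterior summaries and significance

For each non-reference haplotype, OR(t) = exp(β_h(t)) per haplotype copy is
evaluated draw-by-draw on the reporting grid (ages 25-95 by 5) and
summarized by the posterior median and the empirical 2.5/97.5 percentiles.
A haplotype is significant at age *t* when the 95% interval strictly
excludes 1, and overall when that happens at ≥ 1 grid age; replicate
drivers restrict the call to the 55-85 window where mid-life effects are
expected, which also bounds the multiplicity of looks. Smoking, sex and
interaction effects are scalar ORs under the same exclusion rule. No
multiplicity adjustment is applied across haplotypes or ages; the reported
intervals are pointwise.

## Synthetic-data generator

The generator emulates the target study design: 250 unrelated individuals,
4 exams each, a 5-SNP block carrying 5 common haplotypes
(frequencies 0.30, 0.25, 0.20, 0.13, 0.06) and 2 rare ones (0.035, 0.025),
diplotypes drawn under HWE with phase discarded on output. One common
(GGTCC, 0.20) and one rare (GCTAC, 0.035) haplotype are causal; both follow
the same age-varying per-copy log-OR curve — a cubic interpolant through a
fitted real-data profile (OR 0.13 at 25, crossing 1 just after 50, peaking
at 2.52 at 65-70, decaying to ~1.1 by 95). Smoking starts at prevalence 0.3
and persists between exams with probability 0.8 (a two-state Markov chain);
the smoking×GGTCC interaction adds log 2 per copy for smokers, constant in
age. Sex is Bernoulli(0.5) and carries no effect by default. First-exam age
is uniform on (22, 75) with inter-exam gaps uniform on (3, 6) years capped
at 90, so observed ages span roughly 22-90. β0 = logit(0.35) gives a
hypertension-like baseline prevalence. The null scenario zeroes every
genetic and interaction effect and changes nothing else.

What the generator does **not** emulate: linkage-disequilibrium structure
beyond the haplotype frequencies themselves, genotyping error or
missingness, family relatedness, informative examination schedules, secular
or cohort effects on smoking, and any residual within-individual
correlation beyond the shared diplotype. Passing replicate studies
therefore demonstrate correctness of the estimator under the stated
generating model, not robustness to those real-data complications.

## Replicate studies and problem sizes

`run_power_study` generates, fits and scores replicates, reporting
rejection proportions with binomial Monte-Carlo standard errors for the
common causal haplotype, the rare causal haplotype, the interaction, and a
designated null haplotype (ACTAG) whose rejection rate estimates the type-I
error. Replicates with failed fits are recorded and excluded from the
denominator. `scripts/acceptance.py` runs 30 alternative-scenario and 10
null-scenario replicates with the short chains described above — sizes
chosen so a full re-run stays a coffee-break job on a single core while
keeping binomial standard errors below ~0.1.

## Known limitations

* Power for a haplotype×smoking interaction of log 2 is moderate (roughly
  two-thirds in the shipped scenario, as the acceptance script measures):
  only the smoker-carrier records inform it and the shrinkage prior is
  deliberately conservative. Detecting such interactions reliably needs a
  larger effect or more individuals.
* Rare-haplotype power is intrinsically limited by carrier counts (~17
  expected carriers at frequency 0.035 with n = 250).
* If the causal haplotype happened to be the sample's most frequent one it
  would be chosen as reference and its effect absorbed into the baseline;
  with the shipped frequencies this is a ≲0.1% event per replicate.
* The prospective likelihood has no ascertainment correction; the method is
  for cohort, not case-control, sampling.
* Monomorphic-SNP and separation handling in the prescreen are heuristic
  (skip with p = 1; small-ridge refit), adequate for a screen that feeds
  block selection only.
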