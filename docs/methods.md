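# Methods

This note documents the statistical model behind `iecat_rc`, the numerical
choices the implementation makes, what the synthetic-data generator does and
does not emulate, and the known limitations.

## The problem

A case-control GWAS with `n1I` internal cases and `n0I` internal controls can
borrow `n0E` external control genotypes (biobanks, published panels) to gain
power at no sequencing cost. Naive pooling is unsafe: platform, calling-
pipeline and stratification differences shift external allele frequencies
relative to the internal study (the *batch effect*), and because every
external subject is a control, any such shift masquerades as a case-control
association and inflates type-I error — catastrophically so at stringent
significance levels.

## Step 1 — regression calibration of external genotypes

Per variant, external controls are processed in consecutive blocks of at most
`n0I` subjects. For each block, `K` repeats (default 10) randomly pair the
block's external subjects with internal controls (a fresh draw without
replacement each repeat; the final partial block is paired with an
equal-sized random subsample of internal controls). Each repeat fits the OLS
regression

    G_i = b0 + b1 * g_{k(i)} + aI' X_i^I + aE' X_{k(i)}^E + e_i

of the internal-control genotype on the paired external genotype and two
blocks of principal components: the internal subject's internal-genotype PCs
and the paired external subject's external-genotype PCs (`p = 10` components
by default). The `K` coefficient vectors are averaged and used to predict a
continuous calibrated genotype for every external subject in the block;
because external subjects have no internal-PCA coordinates, they are
projected onto the internal PC loadings (after internal-mean centering) for
the `aI` term. Predictions are discretized back to {0, 1, 2} with thresholds
`(a0, a1)` set at the empirical quantiles of the predictions matching the
internal-control frequencies of genotype 0 and of genotypes {0, 1}:
`pred < a0 -> 0`, `a0 <= pred <= a1 -> 1`, `pred > a1 -> 2` (a threshold tie
goes to the middle category, matching the strict/weak inequality pattern of
the defining rules). A monomorphic external block contributes no slope
information; its genotype column is dropped from the regression with
coefficient zero. If all predictions are identical, frequency matching is
impossible and every subject receives the internal-control modal genotype.

Two properties follow. First, *frequency matching*: when the predictions are
continuous (PCs make them so in practice), the calibrated block's category
frequencies match the internal controls' to within `1/block size` — this is
what removes the batch effect, which in the simulation design lives entirely
at the frequency level. Second, *random orientation*: the pairing is random,
so when internal and external cohorts genuinely share a distribution the
fitted slope is noise around zero and the rank map's direction is arbitrary.
Orientation does not matter for frequency-level inference (external subjects
are all controls), but it does mean calibrated and raw external genotypes
can be anti-correlated on half the variants; naive-vs-calibrated p-value
correlations of ~0.4–0.5 under no batch effect are intrinsic, not a defect.

A consequence worth stating plainly: frequency matching replaces external
sampling noise with (a copy of) internal-control sampling noise. The score
test below is therefore calibrated *conditionally on genotypes* — under
phenotype randomness, which is exactly the resampling design of the
validation experiments — while under joint resampling of genotypes with a
fixed phenotype the usual variance formula understates `Var(S)` (by a factor
of 1.5 at the 1:1:2 design) and the calibrated test over-rejects. Power
experiments, which generate fresh datasets per replicate, are unaffected in
their ordering conclusions because all methods share this design.

## Step 2 — covariate-adjusted score test

With phenotype `Y`, covariates `Z` (intercept always included) and genotype
`G` in a logistic model `logit P(Y=1|Z,G) = Z'a + G b`, the score test of
`H0: b = 0` uses

    S = G~' (Y - mu),  G~ = G - Z (Z'VZ)^{-1} Z'V G,  V = diag{mu(1-mu)},
    Var(S) = sum_i G~_i^2 mu_i (1-mu_i),  T = S^2/Var(S) ~ chi^2_1,

where `mu` comes from the covariate-only IRLS fit (convergence when the
largest coefficient step falls below 1e-8, at most 50 iterations; `mu`
clipped to [1e-12, 1-1e-12] so the cumulant-generating function stays
finite). The null fit depends only on `(Y, Z)` and is shared across all
variants of a scan; all per-variant operations are vectorized over variant
columns. Dosage columns coding the major allele are flipped to minor-allele
coding first; the two-sided p-value is invariant to the flip. A variant that
is monomorphic after adjustment returns p = 1 rather than an error.

## Step 3 — SPA and ER calibration

The normal approximation to `S` fails when the case-control ratio is
unbalanced (skewness) or the minor-allele count (MAC) is low (discreteness).

**Saddlepoint approximation.** The CGF of `S` under the null is

    K(t) = sum_i log(1 - mu_i + mu_i e^{G~_i t}) - t sum_i G~_i mu_i,

evaluated with overflow-safe arithmetic. The saddlepoint `t^` solves
`K'(t^) = s` by bracketed Newton iteration (geometric bracket expansion,
bisection fallback, tolerance `1e-8 * max(1, |s|)`), and each one-sided tail
uses the Lugannani–Rice / Barndorff-Nielsen form

    Pr(S < s) ~ Phi(w + log(v/w)/w),  w = sgn(t^) sqrt(2(t^ s - K(t^))),
    v = t^ sqrt(K''(t^)).

`v` uses the square root of `K''`; the exhaustive Poisson-binomial
enumeration oracle confirms this is the correct form. The reported p-value
is two-sided: the upper tail at `|s|` plus the lower tail at `-|s|`, each
with its own saddlepoint. Near the mean (`|w| < 1e-4`) the formula divides
by ~0 and the normal p-value is substituted, flagged as a fallback. A score
at its attainable extreme has no saddlepoint; the implementation returns the
exact product probability of the extreme configurations instead.

Accuracy: against exact (mid-p) binomial tails the SPA is within 1% at
`n = 2000–5500` out to `z = 5.5`, where the normal approximation is 30–60%
off — this is the operating regime of the method. At lattice toy sizes
(`n <= 12`) the uncorrected formula's relative error at typical scores is
~1–15% but grows to ~30% and beyond at deep atoms; lattice-corrected
variants that would fix this are deliberately out of scope, and at such
sample sizes the dispatcher routes to ER anyway. The mid-p tail
(`P(|S| > |s|) + 0.5 P(|S| = |s|)`) is the exact quantity a continuous CDF
approximation targets for a discrete score and is the comparison used in all
enumeration tests.

**Efficient resampling.** For MAC below a threshold (default 10), with
carriers the `m` subjects having `G >= 1`, the p-value decomposes over the
number of cases `D` among carriers,

    Pr(Q >= Q^ | Y,G,Z) = sum_d Pr(Q >= Q^ | D = d) Pr(D = d),

with `Pr(D = d)` the Poisson-binomial law of carrier case counts under the
null probabilities `mu_i`. Summed over `d`, this equals the tail of `Q`
under the product-Bernoulli(`mu_i`) law on carrier phenotypes, which is how
it is computed: exact enumeration of all `2^m` configurations when that is
at most `1e5` (always, for MAC < 10), weighted sampling otherwise. `Q` is
the carrier-restricted score `sum_{carriers} G~_i (y_i - mu_i)` (homozygous
carriers enter through their adjusted dosage); the tail is two-sided in
`|Q|` and includes the observed configuration, so `p > 0` always. The
p-value is invariant to standardizing `Q` (the null weights are fixed across
configurations), verified on enumerable cases.

**Dispatch.** ER when MAC < 10; otherwise SPA whenever external controls are
integrated or the internal case fraction is below 1/3 ("unbalanced" is not
given a sharp definition in the method's original description; this policy is safe because
SPA converges to the normal result when balanced); otherwise the asymptotic
chi-square p. As a numerical economy the SPA is evaluated only when the
asymptotic p-value is below a screening threshold (default 0.25); in the
bulk the two approximations agree to high accuracy, and saddlepoint
corrections large enough to pull a p-value from above 0.25 to below 0.05 do
not occur at the sample sizes involved. Screened-out variants keep the
asymptotic p-value and route label.

## Simulation design

Phenotypes follow `logit P(Y=1) = a0 + 0.5 Z1 + 0.5 Z2 + b G + eps` with
`Z1 ~ N(0,1)`, `Z2 ~ Bernoulli(0.5)`, `eps ~ N(0,1)` a latent frailty kept
additively in the linear predictor (so the marginal law is logistic-normal,
slightly overdispersed relative to plain logistic — deliberately), and
`G ~ Bin(2, q)` per variant. `a0` is solved so the population prevalence is
0.05 (Brent root-finding on a fixed Monte-Carlo sample of 1e6 draws;
prevalence reproduced to ~1e-3). Internal cohorts accrue the design's exact
case/control counts by rejection sampling (draw budget 50x the expectation);
external cohorts are population controls under external MAFs. Six canonical
models cross three `n1I:n0I:n0E` ratios (5000:5000:10000, 6667:3333:10000,
500:5000:10000) with two batch mechanisms applied to a DVS fraction of
variants: external MAF = `min(2q, 0.5)` ("double") or a
`Uniform(0.1q, 4q)` draw truncated at 0.5 ("uniform"). The analysis model
always adjusts the generating covariates `Z1, Z2` (generated for external
subjects too; the combined logistic fit needs complete rows), never `eps`.

**MAF spectrum.** The published experiments sample MAFs from an empirical
mini-exome panel (24,487 variants called in 697 diploid subjects, 9,433 of
them singletons) that cannot be redistributed. The default sampler is a
synthetic stand-in built to match that panel's two defining features — its
granularity and its singleton excess: minor-allele counts `c in {1..697}`
follow a truncated power law `P(c) ∝ c^-gamma` with `gamma` solved once so
that `P(c=1) = 9433/24487 = 38.5%`, and `q = c/1394`. This choice was fixed
from the panel's published summary characteristics before any experiment
was run, and not adjusted afterwards. The naive-integration inflation rates
are sensitive to the upper tail of this spectrum (they are driven by the
fraction of variants common enough for a frequency shift to be detectable),
so rates measured under the stand-in can differ from rates under the real
panel by more than Monte-Carlo error; `sample_maf` accepts an empirical MAF
list whenever one is available. What the generator does *not* emulate:
linkage disequilibrium between variants (the design simulates variants
independently), genotyping error at the call level (the batch effect is
injected directly at the frequency level), and population structure (PCs in
the calibration regression are fitted to structureless binomial genotypes,
where their role is to make the calibrated predictions continuous rather
than to correct stratification). Passing tests therefore demonstrate the
frequency-level mechanism, not robustness to call-level or LD structure.

**Type-I-error harness.** To reach many replicates cheaply the harness
generates `n_variants` genotype sets once, calibrates the external controls
once (calibration involves no phenotypes), and resamples the internal
phenotypes `n_pheno_resamples` times. Resampling draws `Y` from the null
logistic law given the subjects' fixed covariates with `eps` redrawn and the
intercept re-anchored so the expected internal case count equals `n1I`:
under case-control ascertainment the law of `Y` given retained covariates is
the generating logistic law with a shifted intercept, so anchoring to the
design's case fraction (Gauss–Hermite integration over `eps`, Brent solve)
is the retrospective-sampling result, preserves each model's ratio, and is
a valid null (`Y` independent of `G` given `Z`). Rates are reported pooled
and stratified by the differential flag, with per-replicate route counts.

A note on reading the published per-model rates: a rate pooled over a 3%
differential fraction is arithmetically bounded by about
`0.97 * 0.05 + 0.03 * 1 = 0.08`, so published naive-method rates of ~0.4
can only be per-variant rates for the perturbed variants. The acceptance
experiments therefore apply each model's mechanism to every scored variant
(per-variant rejection does not depend on how many other variants are
perturbed) and report the differential-stratum rate.

**Power harness.** Independent datasets per replicate; variant 0 is causal
with log odds ratio `b` (it enters the phenotype law for both cohorts, the
external one under its external MAF), and the remaining variants are null
support for the calibration PCs. Rejection fractions at the requested level
with binomial standard errors.

**Problem sizes used.** The acceptance script runs Models 1, 3 and 4 at 200
genotype sets x 100 phenotype resamples (2e4 replicates per model, about
8–10 minutes total); the test suite runs the same designs at 60 x 50 (3000
replicates, Monte-Carlo SE ~0.004 near 0.05) plus a power comparison at the
1:1:2 design scaled to 1000:1000:2000 with 500 replicates. These sizes were
chosen so each assertion's tolerance is several Monte-Carlo standard errors
wide.

## Numerical and design choices

- `K = 10` pairing repeats: no canonical value exists for `K`; averaging
  stabilizes the slope against pairing noise and gains plateau quickly.
- Quantile thresholds use the sorted-prediction counts `round(f0 * m)` and
  `round((f0+f1) * m)` (inverse-CDF convention); threshold ties go to
  category 1.
- PC provenance: one PCA per cohort; external subjects are projected onto
  internal loadings for prediction. `p = 0` is supported (the calibration
  regression degenerates to intercept + slope, and with a monomorphic or
  atom-valued predictor the discretization can no longer split atoms — use
  `p > 0` whenever frequency matching matters).
- Missing genotypes are mean-imputed per variant (after optional MAF and
  missing-rate QC filters) before any calibration or testing; the
  calibration and testing layers never see missingness.
- Determinism: every stochastic component threads a `numpy` `Generator`
  seeded from the run's recorded seed; identical configurations reproduce
  byte-identical tables.

## Limitations

- Single-variant tests only; no region/set aggregation.
- External controls must come from the same ancestry; PCs here do not model
  admixture or stratification beyond their linear terms.
- The calibrated test's type-I control is conditional on genotypes (see
  Step 1); its unconditional behavior under genotype-level resampling with
  a fixed phenotype is anticonservative.
- The SPA is the plain continuous-variable formula; no lattice continuity
  correction, so deep-tail relative accuracy at toy sample sizes is limited
  (ER covers the low-MAC regime in practice).
- The MAF stand-in reproduces the reference panel's singleton fraction and
  granularity, not its full empirical histogram.
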