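# Methods

## The question

After `k` randomized two-arm trials of a candidate treatment, should it be
endorsed?  `multitrial` compares three families of statistical endorsement
criteria by Monte-Carlo simulation:

1. **Two-significant-trials rule** — endorse when at least two trials are
   individually significant in a one-sided independent-samples t-test at
   level α (default α = 0.025, the one-sided equivalent of a two-sided 0.05
   test plus a direction check).
2. **Meta-analytic confidence intervals** — endorse when the lower bound of
   the 95% CI for the pooled standardized effect exceeds zero, with the CI
   built by the fixed-effect (inverse-variance), DerSimonian–Laird (DSL), or
   Hartung–Knapp–Sidik–Jonkman (HKSJ) method.
3. **Bayes factors** — endorse when the one-sided Jeffreys–Zellner–Siow
   (JZS) Bayes factor of all trial data pooled into two groups exceeds a
   threshold in {3, 10, 50}; a minimum-Bayes-factor bound derived from the
   pooled p-value is evaluated at the same thresholds for comparison.

Each simulated *iteration* is one candidate treatment; decisions are scored
against whether its true standardized effect δ exceeds a clinically
meaningful threshold Δ ∈ {0, 0.15, 0.3, 0.45}, yielding per-criterion
true/false positive rates.

## Generative model

Per iteration, with probability `null_prevalence` ∈ {0.25, 0.50, 0.75, 0}
the treatment is truly inert (δ = 0 exactly); otherwise δ ~ N(0.4, 0.13)
(standardized units; the distribution is untruncated, so ≈0.1% of draws are
negative).  Control observations are N(0, 1) and experimental observations
N(δᵢ, 1), with per-arm sizes n ∈ {20, 50, 100, 400} and k ∈ {2, 3, 5}
trials.  Under the fixed-effects model every trial shares δᵢ = δ; the
random-effects sensitivity variant draws δᵢ ~ N(δ, 0.1).  The default
replication count is 2000 per simulation type.

Truth labels (and CI coverage) always target the iteration-level δ — under
random effects, the mean of the trial-effect distribution — not the
realized trial-level δᵢ.

A null iteration is marked both by the exact-zero sentinel and by a boolean
flag; the flag drives classification, since P(δ = 0) = 0 under the
continuous alternative makes the sentinel unambiguous but a flag is safer.

**Seeding.**  Replication `i` of a run with root seed `s` uses
`default_rng(SeedSequence(entropy=s, spawn_key=(i,)))`.  The null-indicator
uniform and the candidate effect are consumed in fixed order before any
trial data, so runs that differ only in null prevalence share the non-null
effect and data draws replication-for-replication.  This couples prevalence
comparisons (the true-positive rate is then identical up to which
replications are nulled) and makes batches extensible: growing
`n_replications` never changes earlier replications.

What the generator does *not* emulate: unequal arm sizes, non-normal or
heteroscedastic outcomes, dropout, interim looks, publication selection of
which trials exist.  Passing tests therefore certify the statistical
machinery under the idealized model, not robustness of the criteria to
real-world trial pathology.

## Statistical machinery

**t-tests.**  Pooled-variance (Student) statistics; both arms are generated
with unit variance and equal n, so Student and Welch coincide in
distribution here.  Significance uses the strict inequality p < α.  Under
the null with k = 5 and the ≥2-significant rule, the false-positive rate
has the closed form 1 − ((1−α)⁵ + 5α(1−α)⁴), which the pipeline reproduces
empirically (see `analysis/01_null_calibration.py`).

**Effect sizes.**  Cohen's d with sampling variance
v = (n_c+n_e)/(n_c·n_e) + d²/(2(n_c+n_e)).  Hedges' small-sample correction
is available (`hedges=True`) but off by default: at n ≥ 20 per arm it is
negligible, and raw d keeps the estimator aligned with the unit-variance
generative scale.

**Meta-analysis.**  Fixed-effect and DSL intervals use the normal quantile
1.959964; DSL truncates the method-of-moments τ̂² at zero.  HKSJ re-uses
the DSL weights with the weighted residual variance estimator and a
t-quantile with k−1 degrees of freedom, in its plain (unmodified) form: on
perfectly homogeneous inputs the interval has zero width.  This degeneracy
is deliberate — the unmodified estimator is what the named method
prescribes — and is exercised in the tests.  Decisions use the lower bound
of the two-sided 95% interval.

**JZS Bayes factor.**  Cauchy(0, r = √2/2) prior on δ, Jeffreys prior on
the variance, effective sample size N = n₁n₂/(n₁+n₂).  The two-sided BF is
the single integral over the inverse-gamma(½, r²/2) mixing variable g of
the algebraic likelihood-ratio integrand, computed by adaptive quadrature
on a compactified axis with peak-normalized (log-scale) accumulation;
absolute tolerance 1e-10 on the normalized integrand.  The one-sided BF
uses the identity BF₁₀⁺ = BF₁₀ × P(δ>0 | data, H1) / ½, with the posterior
mass obtained by Gauss–Legendre quadrature of the noncentral-t likelihood
against the Cauchy prior in its CDF-transformed variable; panels are placed
around the likelihood peak so both very flat (small n) and very narrow
(large n) posteriors are resolved.  The noncentral-t log-density itself is
evaluated by peak-located quadrature of the chi-square scale-mixture
representation, which stays finite at noncentralities where standard pdf
routines overflow.  Tests verify the implementation against an independent
brute-force Simpson-grid integration of the truncated-prior form to 1e-4
relative error, and the two-sided factor against `pingouin` to 1e-8.

The pooled analysis deliberately ignores trial structure ("all trials
combined"); under the random-effects variant, between-trial heterogeneity
is absorbed into the within-group variance.

**Minimum Bayes factor.**  The −e·p·ln p calibration (local-alternative
bound), reported as BF₁₀ = 1/(−e·p·ln p) for p < 1/e and 1 otherwise.  It
upper-bounds the evidence any local alternative could claim from the same
p-value and is therefore always more liberal than the JZS factor.

**Ties.**  All decision comparisons are strict (p < α, BF > threshold,
lower bound > 0, δ > Δ); ties are measure-zero under continuous generation.
Rates with empty denominators (e.g. TPR in an all-null batch) are reported
as missing with an explicit flag, never as zero.

## Design choices that were genuinely open

- *Student vs Welch per-trial tests*: Student, for the reasons above;
  switching would alter nothing materially under the equal-variance model.
- *Effect estimator*: Cohen's d without correction (see above).
- *Coverage pooling*: the coverage table is indexed by method × n only, so
  cells pool the four prevalence sets; null iterations contribute coverage
  of the truth 0.
- *One-sided BF via mass ratio* rather than direct truncated-prior
  integration: numerically stabler, mathematically identical; the direct
  form is retained as the test oracle.
- *min-BF calibration*: −e·p·ln p is the default used throughout; it is the
  common default of the calibration literature for p-value-only bounds.

## Problem sizes

Test and acceptance runs use deliberately reduced but statistically
meaningful scales, chosen so Monte-Carlo standard errors stay well inside
the asserted tolerances: 500 replications per simulation type for the
coverage table (MC SE ≈ 0.005 per pooled cell), 20,000 replications for the
analytic null calibration (3 SE ≈ 0.0016 around a rate of 0.0059), 2000
replications per run for rate comparisons — the study's own per-type
replication count.  The analysis scripts default to 2000 replications per
type and accept `--reps`/`--seed` overrides.

## Known limitations and observed behaviour

- Under the homogeneous fixed-effects model all three intervals cover the
  true δ at ≈0.95 (fixed ≈ .95, DSL ≈ .96, HKSJ ≈ .95 at every n); DSL
  slightly over-covers because τ̂² ≥ 0 can only widen intervals when Q
  fluctuates above k−1, and plain HKSJ can be narrower than DSL on
  near-homogeneous data.  Clear separation between the methods emerges only
  under genuine between-trial heterogeneity (see
  `analysis/04_random_effects_sensitivity.py`: with τ = 0.1 the
  fixed-effect interval under-covers while HKSJ holds its level).
- The BF > 50 rule's advantage over the two-significant-trials rule at
  Δ = 0.3, n = 20 is real but thin on the TPR axis (≈ +0.007 with ≈ −0.02
  FPR at 20,000 replications); single 2000-replication runs resolve the FPR
  edge clearly and the TPR edge only borderline.
- At Δ = 0.15 the false-positive rate's decline with null prevalence is
  driven by the endorsement-rate gap between small-but-real effects and
  nulls; the gap in the overall FPR is of the order of one MC standard
  error at feasible scales, so analyses should examine the conditional
  rates, not the raw FPR ordering.
- Bayes-factor evaluation costs ≈ 5 ms per iteration and dominates the
  runtime of full-criteria grids; coverage-only studies run two orders of
  magnitude faster.
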