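# Methods

## The model

An incubation group is a set of eggs held at a constant temperature `t`
whose hatchlings were sexed as `M` males and `F` females (intersexes, a
transient ovotestis state whose classification is partly subjective, are
excluded from the binomial totals). Each embryo's sex is treated as an
independent Bernoulli draw with male probability `sr(t)`, so a group
contributes a binomial likelihood term — including its binomial
coefficient, so that reported −ln L values are comparable across software —
and a dataset's log-likelihood is the sum over groups *as listed*: rows at
duplicate temperatures are deliberately not pooled, which leaves the
likelihood unchanged up to a constant but fixes the degrees of freedom of
the saturated model (one fitted proportion per listed row).

Two reaction-norm families are implemented.

**Logistic.** `sr(t) = (1 + exp((P − t)/S))⁻¹`. `P` is the pivotal
temperature (°C); `S` (°C) is one fourth of the inverse of the slope at
`P`, negative for the males-at-cool orientation (TSD Ia). The transitional
range of temperatures between male frequencies `l` and `1 − l` is
`TRT = |S·K_l|`, `K_l = |2 ln(l/(1−l))|`; `l = 0.05` by default, giving the
conventional 5%–95% window.

**Flexit.** A two-branch flexible logistic meeting at `sr(P) = 0.5`:

```
t <  P:  sr = (1 + (2^K1 − 1) exp(4 S1 (P − t)))^(−1/K1)
t >= P:  sr = 1 − (1 + (2^K2 − 1) exp(4 S2 (t − P)))^(−1/K2)
S_b = 2^(K_b − 1) S K_b / (2^K_b − 1)
```

Here `S` is the slope of the curve at `P` itself; `K1` and `K2` shape the
lower and upper transitions independently (acute when positive, obtuse when
negative). `K1 = K2 = 1` recovers the logistic with
`S_flexit = 1/(4 S_logistic)` — the two families parameterize slope
differently, the conversion is exposed as an explicit function and never
applied silently. `K = 0` is undefined and is replaced by `1e-9` with the
sign preserved. The TRT is computed by closed-form inversion of each
branch; tests verify it against brute-force bisection to 1e-6 °C.

### Numerical evaluation of the flexit

The published global fit has `K2 ≈ 200` and the likelihood is nearly flat
in `K2`, so the evaluation must survive `|K|` up to the fitting bound of
1000. For `K > 0` the branch is evaluated entirely in log space
(`log1p`/`logaddexp` identities, with `ln(2^K − 1) ≈ K ln 2` once
`K ln 2 > 30`). For `K < 0` the base `1 − (1 − 2^K) e^u` reaches zero at
finite temperature — the curve attains its asymptote exactly — and is
clamped there. The slope ratio `2^(K−1)/(2^K − 1)` is likewise computed in
log space. Continuity at `t = P`, across the `K → 1e-9` substitution, and
the absence of overflow at `|K| = 1000` are covered by tests.

## Maximum likelihood

Optimization is box-bounded L-BFGS-B (`P ∈ [20, 40]`, `S ∈ [−2, 2]`,
`K ∈ [−1000, 1000]`) from a multi-start grid, with the best three
candidates polished by Nelder-Mead to a likelihood tolerance of 1e-8; ties
are broken by smallest −ln L, then smallest `|K1| + |K2|`. The logistic fit
always runs first and seeds the flexit start at `(P, 1/(4S), 1, 1)` — with
the near-flat `K2` direction a good start is essential. Default starts put
`P` at the egg-weighted mean temperature of mixed-sex groups and try both
signs of `S`. A dataset with no mixed-sex group cannot identify the
parameters and the fit is refused with a pointer to the Bayesian path;
fewer mixed-sex groups than parameters triggers a warning, mirroring the
rule of thumb that `p` parameters want `p` mixed-sex temperatures.

Standard errors come from the inverse of a central finite-difference
Hessian of −ln L (per-parameter relative step 1e-4, halved up to ten times
on non-finite entries); a singular Hessian yields a flagged pseudo-inverse
rather than an exception. Parameters with coefficient of variation above 1
are flagged — on the olive ridley data this reliably flags `K2`. The
logistic path is validated in tests against the exact IRLS solution of a
binomial GLM (statsmodels), both for the estimates and the covariance.

## Intervals

Confidence intervals for `P`, `TRT` and the curve come from resampling the
asymptotic covariance: multivariate-normal draws (Cholesky factor; eigen
fallback when the matrix is only PSD), screened so that `S` — and for the
flexit, `K1 − 1` and `K2 − 1` — keep the sign of the estimate. A sign flip
in `S` would reverse the whole TSD pattern, but the screen necessarily
narrows the interval; the rejection counts are logged, screening can be
switched off to quantify the bias, and rejection above 90% produces a
warning recommending the MCMC route. Default 10,000 draws. The delta method
is deliberately not implemented (its normality assumption fails for the
sign-truncated `S`); the name is reserved and raises with an explanation.

## Goodness of fit and model comparison

Deviance is `D = 2(ln L_S − ln L_M)` against the per-row saturated model,
with `df = n_rows − p` and the asymptotic χ² tail probability. Because the
χ² reference is unreliable at typical sex-ratio counts, a parametric
bootstrap is provided: each replicate redraws every group's male count from
`Binomial(N_i, sr_fit(t_i))`, refits the same family (warm-started at the
fitted parameters), and `p_random` is the fraction of replicate deviances
at or above the observed one. Replicate refits that fail are logged;
seeding is derived per replicate from the master seed. A property test
checks the bootstrap's validity directly: on data simulated from the
fitted model, `p_random` is uniform.

AIC, AICc and Akaike weights (`exp(−ΔAICc/2)`, normalized) compare model
families on one dataset, with the AICc sample size `n` equal to the number
of incubation groups as listed. The grouped-vs-separated dataset test uses
BIC and its weights (*w*-values): one pooled fit with `p` parameters
against per-dataset fits with `k·p` parameters and summed −ln L. For this
comparison the sample size is the number of *distinct* incubation
temperatures — pooled-distinct for the grouped hypothesis, the sum of
per-dataset distinct counts for the separated one. The two conventions are
intentionally different and are exposed through an explicit
`n_convention` argument rather than hidden defaults.

## Bayesian fitting

A component-wise Gaussian random-walk Metropolis–Hastings sampler targets
(likelihood × prior). Each parameter carries a prior specification:
density (uniform or normal) with two shape values, hard support bounds
(`P ∈ [25, 35]` °C, `S ∈ [−2, 2]`, `K ∈ [−500, 500]`), a starting value and
an initial proposal sd (2 for `P`, 0.5 for `S`, `K1`, `K2`). With a
maximum-likelihood fit available the default priors are normal, centered at
the estimates with deliberately wide sds (2 °C for `P`, 1 for `S`, 100 for
`K`) and the chain starts at the estimates; otherwise priors are uniform
over the support. Proposals outside the support are rejected.

During the first 10,000 iterations the proposal sds are adapted every 100
iterations by `exp(κ(acc − 0.234))` with `κ = 1/√batch` — a Robbins–Monro
schedule toward the optimal random-walk acceptance rate of 0.234 — and
frozen afterwards so the summarized chain is Markovian. The default burn-in
equals the adaptation span; a much shorter burn-in (the classical choice is
around 10) is reasonable when starting from the MLE. Summaries are means,
sds (the sd of the chain is the standard error of the parameter) and
empirical quantiles (numpy's default type-7 definition; no thinning), with
derived quantities such as TRT computed from every retained parameter
vector. A prior-vs-posterior overlap diagnostic (1 − total variation
distance of binned samples) warns when the data failed to update a prior.
Unlike the ML path, the sampler accepts datasets without mixed-sex groups —
and even without data, in which case it reproduces the prior (tested by a
Kolmogorov–Smirnov check). The sampler itself is validated against an
analytic conjugate posterior (a pinned-slope single-group setup whose male
frequency has an exact Beta posterior) and, during development, against
brute-force 2-D grid integration of the same posterior.

## Synthetic data

The generator draws `M_i ~ Binomial(N_i, sr_truth(t_i))` — exactly the
sampling model the likelihood assumes — with one independent substream per
replicate derived from the master seed. It backs the bootstrap engine, the
estimator-calibration tests (bias of the refitted `P` on the published
40-group design, interval coverage on a 10-temperature × 50-egg design) and
is exposed for power studies. What it does *not* emulate is deliberate and
bounds what green tests mean for real data: no clutch effects or
between-study heterogeneity (real counts are overdispersed relative to the
binomial — visible in the package's own bootstrap test on the olive ridley
compilation), no temperature measurement error or within-incubator
amplitude, no intersex category, and no shifting of the thermosensitive
period under fluctuating temperatures (out of scope entirely: the package
addresses constant-temperature incubations only).

## Data handling

Input is a comma-separated, UTF-8 table mirroring the layout of the public
TSD incubation database (default columns `Area, Country, RMU,
Incubation.temperature, Incubation.temperature.Amplitude, Males, Females,
Intersexes, Reference`, overridable via a column map). Counts must be
non-negative integers; violations name the offending row. The standard
filter excludes groups whose recorded temperature amplitude exceeds 2 °C
(groups with unreported amplitude are retained — several fixture rows print
no amplitude yet belong to the analysis) and removes intersex individuals
while keeping their groups; both rules log counts of removed groups and
embryos, filtering is idempotent, and nothing is lost silently. A
temperature correction factor column, when present, is stored but never
applied. Duplicate-temperature merging exists solely for the
distinct-temperature BIC sample-size convention and is never applied before
likelihood evaluation.

## Problem sizes and defaults used in the shipped analyses

The packaged fixture has 40 incubation groups (277 males, 168 females, 19
intersexes excluded). The test suite and the acceptance script use 10,000
resampling draws (matching the published figure convention), 100,000 MCMC
iterations with 10,000 burn-in for the East Pacific posterior, 1,000
bootstrap replicates for the deviance tests, and 300–400 replicates for the
calibration studies — sizes at which the Monte-Carlo error is well inside
the tolerances asserted.

## Known limitations

* Only TSD Ia/Ib-shaped (single-pivot) patterns; no two-pivot (TSD II)
  support, and none of the historical Hill / A-logistic / Hulin families.
* The binomial model ignores overdispersion; on heterogeneous compilations
  the bootstrap goodness-of-fit test will reject even when the mean curve
  is adequate, and intervals are accordingly optimistic.
* Sign-coherence screening biases resampling intervals narrow by
  construction; the MCMC route is preferred whenever `S` or a `K` is poorly
  identified.
* The flexit's `K` parameters are weakly identified on small datasets —
  expect large, flagged coefficients of variation rather than errors.
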