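# Methods

## The task environment

Each trial presents a five-bin histogram of "star ratings". Bin probabilities
come from one of three beta distributions on [0, 1], partitioned into
equal-width bins at edges (0, 0.2, 0.4, 0.6, 0.8, 1):

| condition | shape      | bin probabilities g                     | true mean |
|-----------|------------|-----------------------------------------|-----------|
| negative  | Beta(3, 1) | (0.008, 0.056, 0.152, 0.296, 0.488)     | 0.75      |
| positive  | Beta(1, 3) | mirror of the negative vector           | 0.25      |
| uniform   | Beta(1, 1) | (0.2, 0.2, 0.2, 0.2, 0.2)               | 0.50      |

Clicking bin k draws from the beta distribution *conditioned on* that bin's
interval, via the closed inverse-CDF of the truncated distribution. Raw
"positivity scores" are the normalized values times a per-trial multiplier
drawn uniformly from [50, 100], which hides the range from the sampler. All
statistics are computed on the normalized scale; the multiplier enters only
at the draw/display boundary, because bias quantities of magnitude ~0.1 are
only interpretable after normalization. Bins are half-open [a, b) except the
last (closed at 1) — a zero-measure choice for continuous draws. Exact bin
probabilities are used internally; rounding to whole percent happens only in
displays.

Within-bin conditional moments use the beta partial-moment identity
E[X^r·1{a<X<b}] = (∏_{j<r} (α+j)/(α+β+j)) · (F_{α+r,β}(b) − F_{α+r,β}(a)),
so bin means/variances are exact up to CDF evaluation (they agree with
numerical integration of the density to 1e-8 in the tests).

## Allocation policies

- **stratified-deterministic**: quotas N·g_k rounded by the largest-remainder
  (Hamilton) method, ties to the lower bin index. This is the benchmark
  strategy. Note an honest caveat of integer apportionment: the plain
  experienced mean is exactly unbiased only when the quotas are integers. At
  N = 10 the rounding bias in the skewed conditions is ≈1.5e-5 (negligible);
  at N = 20 the allocation (0, 1, 3, 6, 10) implies a rounding bias of
  ≈+0.0096 in the negative condition because the rare bin's 0.16-sample
  quota rounds to zero. The Monte Carlo unbiasedness check therefore runs at
  the 10-sample base budget; the *efficiency* property (see below) is exact
  at every budget.
- **stratified-random**: Multinomial(N, g) — the null model for the pooled
  binomial tests; distributionally identical to simple random sampling.
- **mixture(w)**: Multinomial(N, f(w)) with f_k = (1−w)·g_k + w/5 — the
  cognitive-fencing policy. At w = 0.51 the rare-bin share of the negative
  condition is 0.49·0.008 + 0.51·0.2 = 0.10592 ≈ 11%.

Stratified efficiency: with proportional allocation the estimator variance is
(1/N)·Σ g_k s²_k, versus Var(X)/N for simple random sampling; since
Var(X) = Σ g_k s²_k + Σ g_k (m_k − μ)², the ratio is ≤ 1 always (≈0.09 in
the skewed conditions, 0.04 in the uniform).

## The synthetic experiment generator

The generator's defaults are the study's design constants: 145 participants,
a 50/50 between-subject split into 10- and 20-sample budget arms (the first
⌊split·n⌋ participants after a seeded shuffle get 10), three within-subject
shape conditions in randomized block order with 4 trials each (12 trials,
indexed 1–12), and independent per-trial multipliers.

Participant weights are drawn from Normal(μ_w, σ_w) truncated to [0, 1]; the
truncation is required for a valid mixture weight. Population defaults
(μ_w = 0.51, σ_w = 0.22) are the fitted values.

**Estimate generation** is a deliberate modeling addition — the empirical
phenomenon is that people partially correct their estimates away from the
experienced mean, and the simplest generative mechanism reproducing it is a
linear partial correction with Gaussian report noise:

estimate = clip(experienced_mean − κ·E[bias(w)] + ε, 0, 1) × multiplier,
ε ~ N(0, σ_e),

where E[bias(w)] = Σ f_k(w)·m_k − μ is the analytic expected
experienced-mean bias of the agent's own policy. Defaults κ = 0.5 (about
half the bias corrected, consistent with an observed adjustment of ≈0.06–0.07
against an expected bias of ≈0.115 at w ≈ 0.5) and σ_e = 0.05 (five points
on the 0–100 scale). κ = 0 yields estimates equal to experienced means;
κ = 1 with σ_e = 0 yields fully bias-corrected estimates.

What the generator does **not** emulate: sequential within-trial dynamics,
attention or motivated search, learning across trials, the deterministic
"cover all five bins at least once" tendency (the multinomial mixture covers
the range only on average), response rounding, or real decision noise
structure. Passing tests therefore demonstrate internal consistency of the
model and estimator — not that human data follow this generative process.

## Statistics and exclusion rules

Per trial (normalized scale): sampling bias = experienced − true mean;
estimation deviation = estimate − true mean; estimation adjustment =
experienced − estimate. The identity bias = deviation + adjustment holds to
machine precision and is enforced in tests. The adjustment sign convention
(experienced − estimate) makes corrections *toward* the true mean negative
under negative skew and positive under positive skew.

Preregistered exclusions, applied in order: (1) drop trials in which only
one bin was sampled; (2) drop participants whose estimate is identical on
all their trials; (3) drop participants with ≥ 2 excluded trials. A
participant hit by both participant-level rules is tallied under (2).

Pooled binomial tests: all samples in a condition are pooled across trials
and participants (per-participant testing would not give the tight intervals
the pooled share implies); the exact two-sided p-value doubles the smaller
tail (capped at 1), and the interval is Clopper–Pearson (≥ 95% coverage by
construction). The null for the rare-bin test is the exact g_k = 0.008,
displayed as 1%.

Condition × budget summaries use trial-level means with participant-clustered
percentile bootstrap intervals (default 2000 resamples), replacing
model-based interval estimation with a design-respecting nonparametric one.

Payoff: a linear rule, loss = mean absolute deviation × maximum bonus, which
maps a 13.5% deviation to £1.08 of an £8 bonus. The linearity is an
assumption consistent with that printed pair.

## Hierarchical model and sampler

Likelihood: counts_it ~ Multinomial(N_it, f(w_i)) over the two *skewed*
conditions only — in the uniform condition f(w) = g for every w, so those
trials carry no information about w and only slow mixing. Both budget arms
are pooled in one fit. Trials within a condition are pooled per participant
(lossless: f is condition-specific but trial-invariant).

Priors: w_i ~ TruncNormal(μ_w, σ_w, [0, 1]); hyperpriors μ_w ~
TruncNormal(0.5, 1, [0, 1]) and σ_w ~ Half-Normal(1) — weakly informative on
the unit scale of a mixture weight.

Sampler: adaptive random-walk Metropolis-within-Gibbs on transformed
parameters (logit w_i, logit μ_w, log σ_w, with log-Jacobians). Because the
w_i are conditionally independent given (μ_w, σ_w), all P weights are
proposed and accepted/rejected in one vectorized step per iteration; the
hyperparameters get scalar updates. Proposal scales adapt toward 44%
acceptance in 50-iteration batches during warmup with diminishing adaptation
(±min(0.25, 1/√batch) on the log scale), and are frozen afterwards so the
chain targets the exact posterior. Defaults: 4 chains × 2000 iterations
including 1000 warmup. Chains are seeded from independently spawned
generator streams; fits are exactly reproducible given a seed.

Correctness is contract-checked rather than algorithm-checked: the
log-likelihood and joint log-posterior match independent brute-force
evaluations to 1e-10, and a single-participant posterior mean matches
deterministic grid integration within 0.02. Convergence: rank-normalized
R-hat ≤ 1.05 on both hyperparameters, else a `ConvergenceWarning` is raised
and the fit is flagged `converged = False` (never silent). Near-degenerate
populations (σ_w → 0, μ_w at a boundary) legitimately trip the flag — the
funnel-shaped posterior mixes slowly — while the posterior mean of μ_w still
lands within 0.01 of the boundary truth in the recovery tests.

Parameter recovery at the study design (145 participants, 8 skewed trials
each): absolute bias of the posterior-mean μ_w ≤ 0.05 and ≥ 9/10 interval
coverage at (μ_w, σ_w) = (0.5, 0.2), checked over 10 seeded replications in
the acceptance tests. The population spread σ_w is recovered with a mild
upward bias and below-nominal interval coverage at this design size — with
only 8 informative trials per participant the individual weights are weakly
identified, and the truncation at [0, 1] skews the spread estimate; the
recovery table reports both hyperparameters so this is visible rather than
hidden.

The follow-up regression models |adjustment| on w, condition indicators and
their interaction (OLS point estimates; participant-clustered percentile
bootstrap intervals). With a single condition present it falls back to a
reduced model with a warning.

## Numerical and design choices

- Problem sizes in tests are chosen for statistical resolution at desk
  scale: 1e5–1e6 draws for law-of-large-numbers checks (3–4 standard-error
  tolerances), 10 replications for the recovery study, 2000 bootstrap
  resamples by default.
- Tolerances: exact identities at 1e-10–1e-12; Monte Carlo at k standard
  errors; MCMC-vs-quadrature at 0.02 on a [0, 1] parameter.
- Largest-remainder ties break toward the lower bin index (no ties occur for
  the study's g and budgets).
- Degenerate inputs: empty trial → error; single-bin trials are excluded
  upstream; uniform-only data are rejected by the fit with a clear message;
  all-excluded cohorts produce empty summaries plus a warning, not a crash.
- CSV round trips store reals at 17 significant digits (exact for float64).

## Known limitations

- The estimate-generation mechanism (κ, σ_e) is a modeling convenience; the
  real adjustment process is unknown and likely nonlinear and asymmetric
  between skew directions.
- The multinomial allocation model ignores sequential sampling and cannot
  represent participants who deterministically cover every bin.
- The budget-20 deterministic stratified allocation carries the integer-
  apportionment bias documented above; conclusions about "unbiased
  stratified sampling" hold for the proportional-quota idealization.
- Real-data fitting is supported through the CSV importers but no empirical
  dataset ships with the package.
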