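# Methods

## The simulation model

Every analysis in this package has the same shape: define a population (a
data-generating process), draw a sample of size n from it, apply an
estimator, and repeat many times. The collection of per-experiment
estimates is the sampling distribution; everything else — precision curves,
minimum sample sizes, replication agreement, significance-conditioned
subsets — is a functional of that distribution. The engine keeps the
estimates aligned with their p-values when the estimator is a test, so
conditioning on significance operates on exactly the same simulated
experiments.

Iteration counts default to the scale each experiment family warrants:
20,000 for cheap one-level estimators (means, group proportions), 10,000
for correlation and quantile studies, 5,000 for the two-level reaction-time
pipelines. Every entry point exposes the count, and the test suite runs
scaled-down versions (typically 1,000–5,000 iterations, with tolerances set
from binomial Monte-Carlo standard errors at those counts).

## Populations and their defaults

**Lognormal** (`log_mean=0, log_sd=0.5`): a strictly positive, positively
skewed measurement population. Its closed-form moments
(μ = exp(m + s²/2) ≈ 1.133, σ ≈ 0.604) make it the calibration anchor for
the engine: the SD of the simulated distribution of sample means must match
σ/√n.

**Bivariate normal** with correlation ρ, zero means and unit variances.
Pairs are generated from the Cholesky factor of the 2×2 correlation
matrix. Under ρ = 0, r² ~ Beta(1/2, (n−2)/2) exactly; the package uses this
as an analytic oracle (`pearson_null_within`) so correlation precision
curves and minimum-n searches need no simulation at all, and the simulated
route can be validated against it.

**Beta accuracies** (`mean_p=0.7, concentration=10`, i.e. Beta(7, 3)): the
distribution of participants' true proportions correct. Only the mean of
this distribution is externally constrained; the concentration is a package
default chosen to give a negatively skewed, quite broad distribution on
(0, 1), and it is an explicit knob. Headline probabilities that depend on
the unconstrained shape (e.g. exact tail probabilities of group means) are
therefore treated as qualitative, not exact, targets.

**Onsets** (shifted gamma: shift 40 ms, shape 2, scale 30 ms; quartiles
≈ 71/90/115 ms): a parametric stand-in with the positive skew typical of
ERP onset-latency distributions. Empirical mode stores a latency vector and
resamples it with replacement; all resampling in the package is with
replacement (bootstrap-style).

**Reaction times**: each participant's trials are ex-Gaussian
(Normal(μ, σ) + Exponential(τ); μ=500 ms, σ=50 ms, τ=150 ms for words),
with participant-level parameters drawn from normals truncated at zero
(between-participant SDs 50/10/30 ms) and a participant-specific
word→nonword shift ~ Normal(80 ms, 45 ms). The shift SD is calibrated so
that roughly 96% of participants have a positive trimmed-mean difference,
mimicking the near-unanimous but highly variable lexicality effect seen in
large lexical-decision datasets. Empirical mode stores per-participant
trial vectors and resamples participants with replacement before resampling
their trials (two-level bootstrap).

What the generators deliberately do not model: stimulus-, site-, session-
or time-of-day variance; within-participant parameter drift; trial-level
outlier contamination; and any dependence between a participant's two
conditions beyond the shared μ, σ, τ. Passing tests on these populations
show the pipelines are correct and calibrated under the stated processes,
not that real data follow them.

## Estimators

Trimming uses g = ⌊γn⌋ observations per tail (γ = 0.2 by default), h = n−2g
retained. The winsorized variance replaces each trimmed tail with its
nearest retained order statistic before taking the ddof=1 variance. The
one-sample Yuen statistic is

    t = (x̄_t − μ₀) / SE,   SE = √((n−1)·s²_w / (h·(h−1))),   df = h − 1.

This h-based standard error reduces *exactly* to the classic one-sample t
at γ = 0 (the (1−2γ)√n variant does not when γn is non-integer, which is
why it was not used). At n = 30 with γ = 0.2 under a normal null the
empirical type-I error is ≈ 0.052 — slightly liberal, well within the
0.05 ± 0.01 band the calibration tests enforce.

The Harrell–Davis quantile estimator weights the i-th order statistic by
the Beta((n+1)q, (n+1)(1−q)) probability mass on ((i−1)/n, i/n], computed
as exact regularized incomplete-beta differences (no bootstrap standard
errors). Correlation p-values are two-sided via t = r·√((n−2)/(1−r²)) on
n−2 df; Spearman is Pearson on mid-ranks (ties get mid-ranks, no continuity
corrections). All tests in the package are two-sided.

## Precision and minimum-n searches

Margins are absolute, in the estimator's units. Coverage comparisons use ≥
("at least"), and sample-size searches step by 1 — the interesting answers
(110, 69, and the onset-study sizes) are not multiples of any coarse grid.
`minimum_n_analytic` searches the exact Pearson-null CDF; `minimum_n` and
`replication_minimum_n` are definitional linear scans over simulated
coverages, bit-reproducible because each candidate n gets a spawned child
seed. A simulated first-crossing search inherits Monte-Carlo noise in the
coverage estimates; near a flat part of the curve the returned n can wander
by a few units at 5,000 iterations, which is why the analytic oracle is
used wherever it applies and the simulated route is validated against it
pointwise (3-SE tolerance) rather than by comparing crossing points alone.

## Conditioning on significance

`condition_on_significance` keeps the estimates with p ≤ α. For Pearson
under any ρ the retained set satisfies |r| ≥ r_crit(n, α) exactly, where
r_crit = t_crit/√(df + t_crit²) — the conditional distribution has a hard,
assertable gap, not a statistical one. For the two-level RT null the gap is
carved by the Yuen critical region (|t| ≥ t_crit means
|difference| ≥ t_crit·SE with SE varying per iteration), so the tests
assert the structural facts: every retained p ≤ α, both signs present, and
raw (unconditioned) estimates do fall inside the retained set's empty
neighborhood of zero. The directional (type III) error rate is reported per
sample size, since it varies strongly with n.

## Numerical and design choices

- Randomness: one 64-bit master seed; `numpy` `SeedSequence` spawning gives
  each sample-size block (and each candidate n in a search) an independent
  child stream, drawn sequentially within the single-threaded engine. Same
  seed ⇒ bit-identical results.
- Estimator failures on a degenerate draw (e.g. zero variance in a tiny
  correlation sample) are re-drawn by default — logged, capped at 100
  attempts — so every distribution has exactly `n_iterations` entries
  aligned with its p-values; a `raise` policy is available.
- Skewness is the adjusted Fisher–Pearson coefficient; it is reported as 0
  for exactly degenerate distributions.
- Group-level central tendency is the plain mean for proportion data and
  the 20% trimmed mean (both levels) for reaction times. The group-level
  significance test in the pooled-null pipeline is the one-sample Yuen test
  on participant difference scores against 0 — the natural paired reading
  of a within-participant design.
- Collinear correlation inputs return r = ±1 with p = 0 rather than a
  division-by-zero; zero-variance inputs raise.
- Reports (`sampdist <family>`) write tidy CSVs plus a `manifest.json`
  (config, its SHA-256, seed, package version, wall time); rerunning a
  manifest's config reproduces the CSVs byte for byte. Plots are flag-gated
  and never load matplotlib otherwise. A configured-but-unreadable
  empirical CSV is an error, never a silent fall-back to synthetic data.

## Limitations

- The ex-Gaussian reaction-time population is a parametric stand-in; real
  trial-level datasets carry shape information (multi-modality, sequential
  effects) it cannot produce. The empirical loaders exist precisely so the
  same pipelines can run data-driven.
- Beta-population tail probabilities depend on the concentration parameter,
  which is a default, not an estimate.
- Data-driven resampling treats the loaded sample as the population; when
  the simulated sample sizes approach the loaded sample's size, the
  resampling distributions understate true sampling variability.
- Confidence/prediction-interval coverage, statistical power curves, robust
  two-sample correlation comparisons and mixed-effects model fitting are
  out of scope.
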