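# Methods

## The question and the model

For one user's event timestamps t₁ < t₂ < …, the inter-event times
τᵢ = t_{i+1} − tᵢ (minutes) are heavy-tailed. Each τᵢ is attributed to the
hour-of-day window `[n, n+1)` (UTC calendar hour, n = 0…23) containing its
*initiating* event tᵢ, and the object of study is the conditional density

P(τ | n ≤ t < n+1) = c τ^α, α < −1, above a lower bound xmin.

We write a = −α for the exponent magnitude (the Pareto *shape*; survival
exponent a − 1). The stationarity hypothesis is that a does not depend on
n, even though the event *rate* strongly does. Gaps above 1440 min are
discarded before fitting so that a window's sample cannot reach into the
same clock hour of the following day; the boundary is inclusive
(τ = 1440 is kept, reading the cutoff as an allowed maximum).

Timestamps are treated as server/UTC time. User time zones are unknown, so
window indices are only defined up to a per-user rotation; all statistics
used here (per-window exponents, their spread, pairwise distances) are
invariant under that rotation.

## Estimation

**Shape at fixed xmin.** Continuous maximum likelihood,
â = 1 + n_tail · [Σ ln(τᵢ/xmin)]⁻¹ over the tail τᵢ ≥ xmin. The continuous
(not discrete) estimator is appropriate because τ has 1-second resolution
in minutes — effectively continuous. A sample whose tail values all equal
xmin has a divergent estimate and is reported as degenerate.

**Cutoff-aware shape.** Under the 1440-min cutoff the tail is an *upper
truncated* Pareto, and the plain estimator is biased upward; the bias
grows as a → 1 (for a = 1.59, xmin = 1 it is ≈ +0.04, several standard
errors at n = 10⁴; for a = 1.1 it is ≈ +0.2). `mle_shape(..., xmax=1440)`
therefore solves the truncated likelihood equation

mean ln(τ/xmin) = 1/b − lnR / (e^{b·lnR} − 1),  b = a − 1, R = xmax/xmin,

by Brent root finding on b ∈ [10⁻⁸, 10⁶] (the right-hand side decreases
monotonically from lnR/2 to 0; a tail at least as heavy as log-uniform has
no interior solution and is reported as degenerate). Fits of
cutoff-truncated data — in particular all synthetic-recovery runs — use
this variant; the plain estimator remains the default for data without an
imposed upper bound.

**xmin selection.** Candidate xmins are the distinct sample values,
quantile-thinned to at most 250; the fit minimizing the KS distance
between fitted and empirical tail CDF wins, ties going to the smallest
xmin. Below the 250-candidate cap this equals an exhaustive scan (asserted
against an independent brute-force oracle in the tests).

**Standard errors.** SE(â) = 1/√(n_tail · Var(ln τ)) from the observed
information; for the untruncated Pareto this reduces to the familiar
(â−1)/√n_tail.

**Goodness of fit.** Semiparametric bootstrap: each replicate draws its
tail from the fitted (possibly truncated) Pareto and resamples the
sub-xmin body from the data, keeping the observed tail fraction in
expectation; the replicate is refitted (shape only, at the observed xmin,
by default; full xmin re-selection via `refit_xmin=True`) and the p-value
is the fraction of replicate statistics (KS, or Anderson–Darling A²
against the fitted CDF — the same scheme is used for both, since only the
statistic differs) at least as large as observed. Acceptance means
p ≥ 0.05. With fixed xmin on model data this is exactly calibrated (type-I
rate ≈ 5%, checked on 200 datasets). When xmin was *estimated*, the
default fixed-xmin bootstrap is mildly conservative toward acceptance
(the observed statistic was minimized over xmin, the replicates' were
not); the full re-selection option removes this at ~250× the cost.

**Stationarity statistics.** Per editor j: window exponents α_i, their
mean ⟨α⟩ = Σα_i/N, relative deviations (α_i − ⟨α⟩)/⟨α⟩ (mean zero by
construction); per corpus: relative deviations pooled across editors and
summarized by moment matching a normal (sample mean, sample sd), plus the
collection of ⟨α⟩ values. Pairwise window similarity uses the classical
two-sample KS statistic (via scipy; distances are reported, not p-values,
with the asymptotic p available as a diagnostic). Burstiness uses the
population standard deviation, B = (σ−μ)/(σ+μ), matching the coefficient's
original convention; memory M is the lag-1 Pearson correlation.

## The synthetic generator

Each user is an **alternating renewal process**: from the end of the
previous session, the next initiation arrives from an inhomogeneous
Poisson process whose rate is piecewise-constant over hour-of-day
(a `CircadianProfile`, repeated daily); the initiation triggers K further
events, K geometric on {0, 1, …} with continuation probability p
(the simplest memoryless cascade-size law); successive intra-session gaps
are iid Pareto(shape a, xmin) upper-truncated at 1440 min, drawn by exact
inverse-CDF sampling (the same law as truncate-by-resampling, without the
rejection loop). Sessions never overlap: one person acts sequentially.
This matters — if initiations were an unconditional Poisson process,
concurrent cascades would superpose and the merged stream's gaps would no
longer follow the planted law at all. Truncating the generator's gaps at
the analysis cutoff keeps planted exponents identifiable after filtering.

Timestamps are floored to 1-second resolution (save-stamp granularity)
and ties resolved by minimal +1 s shifts; hour-of-day is the timestamp
modulo 86400 s. In *control* mode, per-hour shape offsets (a sinusoid of
chosen amplitude over the 24 hours) plant an hour-dependent exponent; the
gap's shape uses the hour of the event opening the gap, i.e. exactly the
hour the analysis attributes the gap to. Populations plant super-editors
(initiation rate × 6 by default, which exceeds the 1.25×-mean activity
threshold by construction in expectation) and bots (flagged in the truth
table and given `…Bot` ids so the ingest filter catches them); a root
seed spawns per-user integer seeds by a counter scheme.

**What the generator does not emulate:** weekly seasonality, long-range
rate drifts, per-user time zones, correlated gap sequences beyond the
cascade/wait alternation, and any feedback between activity and content.
Passing tests on this ground truth validate the *estimators and plumbing*,
not claims about real editors.

**Two structural caveats the tests make explicit.**

1. *Wait contamination.* A merged stream's gaps are a mixture:
   intra-session Pareto gaps (fraction ≈ p) and exponential-scale waits to
   the next initiation. When the wait scale overlaps the fitted range, the
   fitted exponent is biased and, at large n, the GOF correctly rejects
   the pure Pareto; xmin selection usually — not always — cuts above the
   wait bulk. Recovery scenarios therefore use high continuation
   probabilities and initiation rates that push waits below xmin; the
   pipeline test on diurnal populations instead *documents* the mixture
   bias (≈ 0.3–0.5 shallow at p = 0.6) and asserts hour-stationarity,
   which survives it.
2. *Within-stream dependence.* Cascade runs make the gap *types* serially
   dependent, so two hour-window samples from one stream are not iid
   draws, and the two-sample KS test is slightly anti-conservative
   (measured pass rates at the 5% level: ≈ 0.93 at p = 0.5, ≈ 0.70 at
   p = 0.8, vs the nominal 0.95, which is recovered exactly in the
   cascade-free limit). The calibration tests carry bounds reflecting
   this.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| cutoff | 1440 min | one day; inclusive boundary |
| min_count | 50 gaps/window | low-statistics window mask; a knob, logged per run — the qualitative "low activity" criterion has no canonical value |
| min_tail_size | 50 | smallest tail fitted |
| xmin candidates | ≤ 250 | quantile-thinned grid cap |
| n_boot | 200 (pipeline), ≥ 100 advised | bootstrap resolution |
| min_edits | 2000 (strict >) | eligibility bar |
| activity_factor | 1.25 (strict >) | super-editor threshold over the *eligible-set* mean (a `reference="all"` switch covers the other reading) |
| min_span_days | 365 (strict >) | one-year filter; span runs from first edit to the corpus's last day, not the editor's last edit |
| generator defaults | a = 2.0, xmin = 1 min, p = 0.6, 12 users, 400 days | a mid-range empirical exponent and a typical multi-year corpus at test-friendly scale |

## Scenario sizes (tests and acceptance script)

Chosen as the smallest sizes at which each effect is resolved at 3
standard errors: posting-stream exponent recovery uses one user with
planted a = 1.1, flat 12 initiations/h, p = 0.95, 2200 days (≈ 2×10⁴ gaps
— the mean truncated gap at a = 1.1 is ≈ 2.5 h, so heavy-tailed streams
need long spans, not high rates); planted-1.59 recovery uses 4 users ×
≈ 1.4×10⁴ gaps; the stationary/heterogeneous contrast uses 3200-day
streams giving ≈ 2000 gaps per hour window; GOF calibration uses 200
(tests) / 100 (script) Pareto datasets of n = 1000; the K-S null uses 24
windows of n = 2000 with a 100-replicate simulated null of the max
off-diagonal statistic.

## Known limitations

- No alternative tail families (lognormal, stretched exponential) or
  likelihood-ratio comparisons; a Pareto GOF acceptance is not evidence
  against those.
- The per-window fit treats gaps as independent; within-stream dependence
  (caveat 2) mildly widens true sampling spreads relative to the
  asymptotic SEs.
- Bot detection is heuristic (explicit list ∪ case-insensitive "bot"
  suffix ∪ flag column); IP detection is syntactic.
- Edit-log ingestion expects delimited text with epoch-second timestamps;
  XML dumps and API pagination are out of scope.
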