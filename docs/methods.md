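# Methods

This note documents the statistical model behind `rmtl`, the numerical and
design choices that are not forced by the mathematics, what the simulator
does and does not emulate, and the known limitations.

## Model and estimators

Subjects experience one of two terminal causes (the event of interest,
coded 1, and a competing event, coded 2) or are right-censored (coded 0).
Censoring is assumed independent of the event process; the package assumes
no left truncation and exactly two arms in all two-sample procedures (cause
codes above 2 are tolerated by the estimators but untested territory).

The all-cause survival Ŝ(t) is the Kaplan–Meier product-limit estimate
treating both causes as failures. The CIF of cause j is the Aalen–Johansen
form Î_j(t) = Σ_{t_i≤t} (d_ij/n_i) Ŝ(t_{i−1}), accumulated over distinct
times with at least one event of any cause. Ties are handled by the standard
convention: all events at t_i share the risk set n_i, and censorings tied
with events are processed after them. Curves are right-continuous step
functions; left limits are values at the previous event time. Both causes'
curves share one time grid, which makes the identity Î₁+Î₂+Ŝ = 1 hold
exactly (to round-off) on every sample, censored or not.

The pointwise CIF variance is the counting-process (Aalen-type) estimator in
its standard textbook form (the sum of an overall-survival part, a
cause-specific-increment part, and their cross term). The literature states
this estimator in several algebraically equivalent layouts and the choice
cannot be settled from a formula alone, so it is validated two ways: exactly
against lifelines' Aalen–Johansen implementation (machine precision on
tie-free data), and against the empirical variance of the CIF estimate over
simulated replicates — the acceptance suite requires agreement within 15%
at n = 200 and observes ~1–2%.

RMTL is the exact step-function integral of Î₁ on [0, τ] (left-continuous
rectangle rule, final interval capped at τ; τ need not be an event time; the
moment integral ∫ t Î₁ dt is evaluated in closed form per interval, not by
quadrature). Its variance uses the moment construction
var = 2τ∫Î₁ − 2∫tÎ₁ − (∫Î₁)², a **per-observation** quantity; the
estimator's variance is var/n. Both scales are carried on the result object
because the sample-size formula consumes the per-observation scale while
confidence intervals need the estimator scale. RMSTc (mean time free of any
event) uses the same construction applied to Ŝ with
E[min(T,τ)²] = 2∫tŜ dt. Confidence intervals are normal-approximation at
95% by default; nothing in the machinery pins the interval construction, and
the normal approximation is the scale on which such results are customarily
reported.

The default restriction time is τ = min over arms of the largest
event-of-interest time, a rule that guarantees both CIFs are informative on
the whole window. A user-supplied τ must not exceed the observed support;
violations raise an error naming the largest usable value.

## The two tests

**Diff** refers Z = Δ̂/√(var₁/n₁ + var₂/n₂) to N(0,1), with Δ̂ the RMTL
difference (group 2 − group 1) at τ. **sDiff** accumulates the running
integrated CIF difference Δ̂(t_r) over a grid and refers
Q_S = sup_r |Δ̂(t_r)|/σ̂(τ) to the distribution of the supremum of absolute
standard Brownian motion on [0,1].

Grid: pooled distinct event times of either cause in either arm inside
(0, τ], with τ appended as terminal knot. The integrand only changes at
event-of-interest times, so finer pooling does not change the path's
suprema, but pooling guarantees Δ̂(τ) equals the Diff effect estimate
exactly (asserted to 1e−12 in the tests).

Scale: σ̂²(τ) combines the pointwise Aalen variances across grid intervals,
with a uniform correlation coefficient ρ applied to all cross-interval
terms; with s_i = (t_{i+1}−t_i)√(V̂₁₂(t_i)+V̂₁₁(t_i)) it collapses to
(1−ρ)Σs_i² + ρ(Σs_i)², which is how it is computed. ρ is not estimable
without assuming the underlying CIF law; it defaults to 0.5 (a value known
to keep the test's size near nominal while retaining power) but is exposed
as a parameter. Monte-Carlo profiling during development showed that with
this scale σ̂(τ) sits some 10–15% below the true standard deviation of
Δ̂(τ) (the true inter-interval correlation exceeds 0.5); the larger critical
value of the sup-|BM| reference (2.2414 vs 1.96 at 5%) compensates, and the
realized size at 0% censoring is close to nominal rather than conservative.
A practical consequence: under a proportional-type alternative the power of
sDiff is statistically indistinguishable from Diff's rather than strictly
below it, while under crossing CIFs sDiff is clearly superior and under
heavy censoring it corrects Diff's size inflation (both reproduced in the
acceptance suite).

The sup-|BM| tail is the alternating series
P[sup|M|>x] = 1 − (4/π) Σ_a (−1)^a/(2a+1) exp(−π²(2a+1)²/(8x²)), truncated
at m = max(⌈(x√2/π)√(log(1/(πε))) − ½⌉, 1) with ε = 1e−10 by default; the
result is clamped to [0,1]. The series is validated against simulation of
10⁵ discretized Brownian paths with 10⁴ steps each.

## Sample size

Diff's total n is closed-form. sDiff's multiplies it by ξ = η²/η̃², where
η̃ = z_{1−α/2} + z_{1−β} and η solves
Y(η) = Φ̄(V−η) + e^{2Vη} Φ̄(V+η) = 1−β with V the sup-|BM| critical value
at α. Two numerical points: the exponent in the power equation is written
with V throughout (the derivation's drift-free symbol), and the derivative
used by Newton–Raphson is the analytically correct
Y′(x) = φ(V−x) + 2V e^{2Vx} Φ̄(V+x) − e^{2Vx} φ(V+x), verified against a
numerical derivative. Newton–Raphson starts at η̃ and is safeguarded by
bisection inside [η̃, η̃+5]; V itself is found by Brent root search of the
tail series on [1e−3, 10]. ξ depends only on (α, power) — the effect-size
and incidence terms cancel — and the tests assert both that ξ is identical
across unrelated pilot inputs and that ξ ≥ 1 over a grid of designs.
Per-group sizes are rounded up separately (even totals at r = 1).

Pilot-based design estimates Δ and the per-observation variances from data
at a chosen τ. The pilot τ and the design τ must be the same window: the
validation loop in the acceptance suite therefore fixes a design window
(τ = 15 for the stock proportional scenario, comfortably inside the support
at every realistic n) for both the pilot estimation and the power
simulations, as a real trial's follow-up duration would be. The pilot draw
is large (20 000 per arm) so that pilot sampling error does not masquerade
as formula error.

## The simulator

Failure cause is drawn first (Bernoulli, plateau p₁ = 0.7 for the event of
interest by default), then the latent time from that cause's conditional
piecewise-Weibull distribution by closed-form inverse transform on the
cumulative hazard, with continuity enforced at segment breakpoints.
Censoring is Uniform(0, c), identical in both arms; c is calibrated by
common-random-number root search to hit a target rate (0/15/30/45% are the
conventional benchmarks). Replication studies give every replicate its own
child stream of one seeded root generator and run all requested tests on the
same data, so method comparisons are paired; a fixed seed reproduces every
table bit-for-bit.

Six stock scenarios cover the canonical two-sample shapes: (A) identical
arms, (B) proportional sub-distribution-hazard difference — built as an
exact SDH-ratio-1.8 transform of the baseline CIF and then represented as a
five-segment piecewise-Weibull fit (max CDF error ~1e−4), which forces the
plateaus to differ (0.7 vs 0.886); the ratio 1.8 places power at n = 100
per arm in the mid-0.9s, the regime published benchmarks for this shape
occupy — (C) late-diverging non-proportional difference, (D) early
difference whose gap freezes, (E) late difference, (F) crossing CIFs whose
signed integrated difference nearly cancels at the usual restriction times
(the construction was checked against the closed-form CIFs, crossing near
t ≈ 7.4). Time units are arbitrary; the competing event is Exp(mean 10)
throughout so that scenarios differ only in the event of interest.

What the simulator does *not* emulate: covariate structure, dependent or
arm-specific censoring, staggered accrual, more than two causes, and ties
(times are continuous). Passing tests therefore validate the estimators and
tests under clean independent censoring; they say nothing about, e.g.,
informative-censoring robustness.

Problem sizes used by the simulation-based validations (chosen to keep a
full run on one CPU in the low tens of seconds while leaving Monte-Carlo
error well below the margins being tested): 5000 replicates at n = 100+100
for size, 2000 at n = 50+50 for the power orderings, 5000 at n = 200 for
the variance oracles, 1000 for observed power at calculated sizes.

## Known limitations

* The sDiff p-value uses the sup-BM approximation at every n; no
  small-sample correction is applied.
* σ̂(τ) inherits the arbitrariness of the fixed ρ; users comparing against
  other implementations should expect mild sensitivity of Q_S to ρ and to
  the grid convention.
* Confidence intervals are normal-approximation; no bootstrap alternative.
* One-sided tests are not offered.
* The CSV reader accepts cause codes {0,1,2} only; multi-cause estimation is
  possible through the API but outside the tested envelope.
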