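# rmtl — restricted mean time lost for competing-risks data

`rmtl` is a Python toolkit for analysing time-to-event data with competing
risks through the **restricted mean time lost (RMTL)**: the area under a
cause's cumulative incidence function (CIF) on a window `[0, τ]`, i.e. the
average time a patient loses to that cause within the window. Unlike the
sub-distribution hazard ratio, the RMTL difference between two arms is an
absolute, clinically interpretable number of time units, and the tests built
on it need no proportional-hazards-type assumption. The package is aimed at
biostatisticians analysing trials or registries with competing endpoints
(e.g. treatment-related death vs. relapse) and at trial designers who need
sample sizes for RMTL-based comparisons.

## What it computes

For subject-level records `(time, status, group)` with `status` 0 = censored,
1 = event of interest, 2 = competing event:

* **Estimation** — all-cause Kaplan–Meier Ŝ(t); Aalen–Johansen CIF
  Î_j(t) = Σ_{t_i ≤ t} (d_ij / n_i) Ŝ(t_{i−1}) with the counting-process
  (Aalen) pointwise variance; RMTL = ∫₀^τ Î₁(t) dt with moment-based
  variance  var = 2τ∫Î₁ − 2∫tÎ₁ − (∫Î₁)²  (per observation; the estimator's
  variance is var/n); RMSTc, the restricted mean time free of any event,
  with the identity RMTL₁ + RMTL₂ + RMSTc = τ.
* **Two-sample tests on the RMTL difference Δ** —
  **Diff**: Z = Δ̂ / √(var₁/n₁ + var₂/n₂) against N(0,1);
  **sDiff**: Q_S = sup_{t_r ≤ τ} |Δ̂(t_r)| / σ̂(τ), the running integrated CIF
  difference standardized by a ρ-correlated combination of Aalen variances
  (ρ = 0.5 by default), referred to the distribution of sup|M(t)| of standard
  Brownian motion on [0, 1] via its alternating-series tail.
* **Sample size** — closed form for Diff,
  n = (1+r)(z_{1−β}+z_{1−α/2})² / (Δ²/(σ₁²+r⁻¹σ₂²)); for sDiff the Diff size
  is inflated by ξ = η²/η̃², where η solves the drifted-Brownian
  boundary-crossing power equation by Newton–Raphson and η̃ = z_{1−α/2}+z_{1−β}
  (ξ ≈ 1.057 at α = 0.05, power 0.8). Design parameters can be supplied
  directly or estimated from pilot data, including a τ-sweep.
* **Simulation** — a piecewise-Weibull competing-risks generator with six
  stock scenarios (null, proportional sub-distribution-hazard difference,
  non-proportional, early, late, crossing CIFs), Bernoulli cause allocation
  with plateau p₁ = 0.7, calibrated uniform censoring, and drivers for
  type-I-error / power / observed-power studies.

## Worked example

Simulate a 150-per-arm trial under the proportional-difference scenario with
~15% censoring, then analyse it:

```python
import dataclasses
import numpy as np
import rmtl as R

config = R.load_scenario("B", n1=150, n2=150)
config = dataclasses.replace(
    config, censor_upper=R.calibrate_censoring(config, 0.15, seed=3)
)
s1, s2 = R.sample_pair(config, np.random.default_rng(42))
print(R.analyze(s1, s2).summary())
```

```
Two-group RMTL analysis at tau = 28.4364 (min_last_event_of_interest)
  RMTL  1: 13.705 (12.023, 15.387)
  RMTL  2: 19.154 (17.812, 20.496)
  RMSTc 1: 9.162   RMSTc 2: 8.073   difference: -1.089
  RMTLd (2 - 1): 5.449 (3.297, 7.601)
  Diff : Z = 4.963, p = 0.0000
  sDiff: Q_S = 5.143, p = 0.0000
```

Within 28.4 time units, arm 2 loses on average 5.45 more units to the event
of interest than arm 1 (95% CI 3.30–7.60); both tests reject the null of
equal RMTL. Treating the simulated data as a pilot study, the sample size for
a confirmatory trial at α = 0.05 and power 0.8:

```python
params = R.pilot_design_from_data(s1, s2, 28.4364)
R.samplesize_diff(params).n_total    # 96
R.samplesize_sdiff(params).n_total   # 102  (xi = 1.0573)
```

The same workflow is available from the shell:

```bash
rmtl analyze --input trial.csv --tau auto
rmtl test --method sdiff --input trial.csv
rmtl samplesize --method sdiff --pilot trial.csv --tau 28.4 --power 0.8
rmtl simulate --scenario A --n1 100 --n2 100 --reps 5000 --seed 42
```

An optional real-data check against the 408-patient bone-marrow-transplant
data (shipped with the R package *timereg*; not redistributable here) runs
automatically when an export is placed at `data/bmt_timereg.csv` with columns
`time` (months), `status` (0/1/2) and `group` (No/Yes).

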