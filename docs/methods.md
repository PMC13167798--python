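# Methods

This note records the models, the synthetic-data generator, the numerical
choices and the known limitations of `strawtrack`, in the spirit of a
statistical software methods appendix.

## 1. Measurement model

### Path-loss calibration

Received signal strength (RSSI, dBm) at a single wall-mounted receiver is
related to tag distance d (m) by the log-distance propagation model

    RSSI = TxPower − 10 · n · log10(d) + e,

with `TxPower` the received power at the 1 m reference distance and `n` the
path-loss exponent. Both are estimated by ordinary least squares of RSSI on
−10·log10(d) over calibration records (`PathLossRegressor`); the fit is
refused when fewer than two distinct distances are present (the two
parameters are then unidentifiable). Distance is recovered by the exact
inverse `d = 10^((TxPower − RSSI)/(10 n))`, which is strictly decreasing in
RSSI. Implausibly large distances (default > 50 m) are flagged, never
altered. No smoothing, clipping or multipath correction is applied.

### Hourly movement metric

Movement is the within-hour sum of absolute changes in estimated distance
between consecutive detections of the same pig, converted to cm·h⁻¹. Each
increment is credited to the pig/day/clock-hour of the **later** detection
(increments may cross hour and midnight boundaries; each is counted exactly
once, and the rule is stable under row re-ordering). An hour is *valid* iff
at least one detection falls inside it; invalid hours carry no movement
value and are excluded from inference — absence of detections means absence
of positioning information, not confirmed inactivity. Days and hours are
labelled in the study's local timezone; day 1 starts at the configured
study start date.

Two structural properties of this metric matter for interpretation:

* **Subsampling monotonicity.** Deleting detections can only decrease an
  hour's total (triangle inequality), so dropout deflates the metric.
* **Noise accumulation.** Independent RSSI noise *inflates* the metric: a
  noisy stationary tag accrues |Δd| at every pair. The field system this
  emulates suppressed that bias by quantizing distance into detection
  zones; that filter is deliberately out of scope here, so absolute levels
  from the raw trajectory pipeline depend on the configured RSSI noise
  (default 0.5 dB). The model-level generator (`simulate_hourly`) is not
  affected — it draws the hourly response directly.

## 2. Hourly mixed model

Valid hourly records y_idh (pig i, day d, hour h) are modelled as

    y_idh = μ + Day_d + Hour_h + (Day×Hour)_dh + b_i + ε_idh,

with b_i ~ N(0, σ²_pig) and, within each pig × day block, a stationary
AR(1) residual: Var(ε) = σ²_res, Corr(ε_h, ε_h') = ρ^|h−h'| over the
observed (possibly gappy) hours — the standard Markov extension of discrete
AR(1) to missing time points. Residuals are independent across pig-days.
Estimation is REML. The criterion evaluated is

    −2ℓ_R = log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r + (n − p)·log 2π,

with β profiled out by GLS and r = y − Xβ̂.

**Fixed-effect parameterisation.** Internally X is the saturated cell-mean
coding over the *observed* day × hour cells, which is full rank by
construction; every reported quantity is an estimable function of cell
means, so results are invariant to coding choice. Rank bookkeeping for the
interaction uses the dimension of the observed-cell space orthogonal to the
additive intercept + day + hour span (437 on a complete 20 × 24 grid; one
empty cell removes exactly one dimension).

**Computation.** For the Markov correlation the block inverse is
tridiagonal in closed form, and the pig intercept is a rank-one Woodbury
update per pig, so one likelihood evaluation is O(n) plus a p × p Cholesky;
no n × n matrix is formed. The optimiser is bounded quasi-Newton (L-BFGS-B)
over (log σ²_pig, log σ²_res, atanh ρ) from three spread starting points
(guarding against likelihood-ridge flatness), followed by an exact
closed-form profile step for the overall variance scale. Non-finite
objective values are returned as +∞ (optimiser-safe); non-convergence is
reported, never silent. The kernels are verified in the test suite against
dense brute-force V-matrix oracles to 1e−6 and reduce exactly to OLS when
ρ = 0 and σ²_pig = 0. With only one observation per pig-day block ρ is
unidentifiable and is fixed at 0 with a warning.

**Inference.**

* *LSMeans* are equal-weight averages of cell means over the other factor;
  a level whose average would involve an unobserved cell is flagged
  inestimable rather than silently re-weighted. CIs use the t distribution.
* *Type-3 F tests* are Wald tests of the corresponding contrast matrices;
  the interaction contrast space is the orthocomplement described above.
* *Slice tests* test equality of the observed hourly means within each day
  (num df = observed hours − 1).
* *Denominator df* follow the containment idea: n − rank([X, pig
  indicators]), with the rank overlap between the two partition designs
  computed exactly as the number of connected components of the cell × pig
  bipartite graph. This is an approximation to SAS's containment rule under
  missing-cell patterns; matching a particular printed df is not a goal.
* *BLUPs* are conditional modes b̂_i = σ²_pig · 1ᵀV_i⁻¹(y_i − X_iβ̂); their
  prediction variance includes the fixed-effect uncertainty term, so pigs
  with few hours shrink harder toward 0 with wider intervals.
* *ICC* = σ²_pig/(σ²_pig + σ²_res); ρ is deliberately excluded — the ICC
  partitions marginal variance between the persistent pig level and
  everything else, and is invariant to response rescaling.

Wald F p-values condition on the estimated variance components (as in
PROC-MIXED-style output); with moderate numbers of random-effect levels
they are mildly liberal. The null-calibration test in the suite quantifies
this: over 200 null simulations the covariate p-values are statistically
indistinguishable from uniform at the 1 % KS level.

## 3. Environmental model

Climate records are averaged to day × timeline blocks (Timeline 1 =
00:00–07:00, 2 = 08:00–15:00, 3 = 16:00–23:00; the blocks partition the
day). Because PM1, PM2.5 and PM10 are near-duplicates in barn air, a screen
retains only PM2.5 when **all** pairwise Pearson correlations exceed 0.95
(threshold configurable; zero-variance columns are flagged). Movement is
averaged to pig × day × timeline means over valid hours, with n_hours
(1–8) recorded as the weight.

The covariate model is

    dist_mean = Day + Timeline + temp + rh + PM2.5 + u_pig + u_DayTL + e,

with independent crossed random intercepts for pig and day-by-timeline and
residual variance σ²_res/n_hours. Day enters as a factor, not a trend.
Weights are relative and are normalised to mean 1, so proportional weight
vectors give identical fits (σ²_res then refers to an average-weight
observation). REML uses the same machinery through a Woodbury identity
with a q × q inner solve (q = pigs + blocks). Covariates that are constant
or collinear with the factor structure are flagged inestimable and
excluded from the fit rather than aborting it; movement blocks without a
matching environmental block are dropped with a logged count. Type-3 tests
reduce to tests of coefficient blocks because the model has no
interactions; denominator df are n − rank([X, Z_pig, Z_DayTL]).

The random DayTL intercept absorbs block-level shocks, so covariate effects
are identified only through block-to-block covariate variation in excess of
that shock — with nearly constant indoor climate, covariate tests are
expected to be null, which is the scientifically relevant behaviour.

## 4. Synthetic-data generator

The generator emulates the study conditions and is the package's test bed.

* **Study layout:** 16 pigs × 20 days × 24 h (7,680 possible cells).
* **Diurnal truth:** single-harmonic cosine through the two anchor values
  666.0 cm·h⁻¹ at 01:00 and 1,025.5 cm·h⁻¹ at 15:00 — the only two hourly
  means available to anchor a profile; a one-harmonic curve is the smallest
  model through them.
* **Hourly model truth:** σ²_pig = 15,773, σ²_res = 38,884, ρ = 0.19.
  Day effects iid N(0, 40²) centred to sum to zero (the reported day range,
  roughly −21 %/+27 % of the daily mean, is of this order); day × hour
  interaction effects iid N(0, 30²) centred to zero — a deliberately small
  modulation consistent with a significant but weak interaction.
  Negative responses are *not* floored by default: the analysis model is
  linear-Gaussian and flooring would bias variance-component recovery; a
  flooring switch exists for realism studies.
* **Missingness:** cells are invalidated completely at random
  (`missing_prob`); the real mechanism is unknown, so MCAR is the neutral
  choice, and the full grid is always emitted with validity flags so
  conservation can be checked exactly.
* **Trajectory:** a 1-D reflected random walk along the pen's long axis
  (14.3 m pen, receiver at the 7.15 m midpoint), positions every
  U(3, 5) s, hour-dependent Gaussian step scale calibrated so the expected
  per-hour path length equals the diurnal profile times a pig's baseline
  multiplier (lognormal across pigs, CV 0.15). 1-D is the natural choice
  for a single range-only receiver on the long wall. Reflection is
  implemented by billiard unfolding of the free walk.
* **Detections:** RSSI = TxPower − 10·n·log10(max(d, 0.1 m)) + Gaussian
  noise; the 0.1 m floor avoids log(0) (tag-to-antenna separation never
  reaches zero physically). Detections are dropped independently with
  probability `dropout_prob` (default 0.7 — a plausibility choice: a
  3–5 s cadence over 16 pigs × 20 d would produce far more raw records
  than a realistic event log retains; the true rate is unknown).
* **Climate:** records per day uniform in 80–97; temperature 16.05 ± 1.55 °C
  and humidity 71.05 ± 4.66 % (moment-matched to the reported weighted
  summaries); the three PM fractions share one latent standard-normal
  factor with loading √0.98 so pairwise correlations target 0.98, means in
  the observed ratios 6.37 : 9.76 : 14.54 µg·m⁻³, negatives truncated at 0
  (truncation leaves the realised correlations in the 0.95–1.0 band).

What passing tests on these data do **not** show: robustness to non-MCAR
missingness, to multipath/orientation RSSI artefacts beyond white noise, to
2-D movement tangential to the receiver axis (range-only sensing
under-measures it), or to behavioural feedback between climate and
movement. Those are properties of the field system, not of the estimator.

## 5. Problem sizes used in the checked experiments

Parameter recovery simulates 24 replicates of the complete study grid
(n = 7,680 each) and compares the replicate-mean ICC and ρ to the
generative values within ±0.03 — at 16 pigs the single-replicate σ²_pig
estimate has a coefficient of variation near √(2/15) ≈ 36 %, so averaging
over replicates is essential. Null calibration of the environmental model
uses 200 replicates at 8 pigs × 10 days; oracle-equivalence checks use
instances of ≤ 50 observations where dense linear algebra is exact and
fast. These sizes are the package's own choices for tight, informative
checks.

## 6. Known limitations

* Containment df is rule-based as described; Kenward-Roger or Satterthwaite
  adjustments are not implemented.
* Heterogeneous AR(1), random slopes and Bayesian estimation are out of
  scope.
* The movement metric measures range changes to a single receiver; true
  displacement tangential to the receiver axis is under-estimated by
  construction.
* Wald-type tests condition on estimated variance components (mild
  liberality with few random-effect levels).
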