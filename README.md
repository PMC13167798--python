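# strawtrack

Movement sensing and longitudinal mixed-model analysis for finishing pigs
housed on deep straw bedding.

Pigs in enriched (deep-straw) finishing systems show strong diurnal activity
rhythms, day-to-day modulation of those rhythms, and persistent individual
differences in baseline movement — structure that matters when RFID-based
movement monitoring is used for welfare and health surveillance. This
package implements the complete analysis chain for such data, for
researchers in precision livestock farming and applied ethology:

1. **Calibration** (`strawtrack.sensor`) — RSSI readings are converted to
   tag-to-receiver distance with the empirical log-distance path-loss model
   `distance = 10^((TxPower − RSSI)/(10·n))`, where `TxPower` is the
   received power (dBm) at 1 m and `n` the path-loss exponent, both
   estimated from calibration records by least squares
   (`PathLossRegressor`).
2. **Movement metric** — consecutive distance estimates are differenced and
   the absolute increments summed per clock hour (`aggregate_hourly`),
   giving hourly movement in cm·h⁻¹ (4 m → 2 m → 5 m counts as 5 m moved).
   Hours with no detections carry no positioning information and are
   flagged invalid, not zero.
3. **Hourly mixed model** (`strawtrack.lmm.MovementLMM`) — REML fit of

   y_idh = μ + Day_d + Hour_h + (Day×Hour)_dh + b_i + ε_idh,

   with a random pig intercept b_i ~ N(0, σ²_pig) and AR(1) residuals
   within each pig × day (lag-1 correlation ρ, marginal variance σ²_res;
   correlation ρ^|Δh| across gaps). The fitted model yields least-squares
   means with 95 % CIs, Type-3 F tests and within-day slice tests
   (containment denominator df), pig BLUPs with prediction intervals, and
   the intraclass correlation ICC = σ²_pig/(σ²_pig + σ²_res).
4. **Environmental model** (`strawtrack.env.EnvLMM`) — barn climate
   (temperature, humidity, PM1/PM2.5/PM10) averaged to day × timeline
   blocks (00–07, 08–15, 16–23 h), a collinearity screen that keeps only
   PM2.5 when the PM fractions are near-duplicates (pairwise r > 0.95),
   and a weighted mixed model of block-level movement on the retained
   covariates with crossed pig and day-timeline random intercepts
   (residual variance σ²/n_hours).

Because event-level barn data of this kind are rarely shareable, the
package includes a first-class synthetic-data module
(`strawtrack.synthetic`) that emulates the whole measurement process — a
reflected random walk along the pen, 3–5 s detection cadence with dropout,
RSSI noise, a cosine diurnal profile troughing at 01:00 (666 cm·h⁻¹) and
peaking at 15:00 (1,025.5 cm·h⁻¹), pig-level heterogeneity, AR(1)
hour-to-hour correlation, and near-collinear PM fractions — so every stage
is testable end to end.

The mixed-model engine is written for this covariance family: the AR(1)
block inverse is tridiagonal and the pig intercept a rank-one update, so a
REML evaluation on the full 16 × 20 × 24 grid costs milliseconds and a full
fit a couple of seconds. The test suite checks it against dense
brute-force V-matrix oracles.

## Worked example

```python
import strawtrack as st
from strawtrack.lmm import MovementLMM

truth = st.default_truth(seed=2)                       # study-scale generative truth
hourly = st.simulate_hourly(truth, n_pigs=16, n_days=20, missing_prob=0.0, rng=2)
records = st.analysis_table(hourly)                    # valid hours only
fit = MovementLMM().fit(records)

print(f"variance components: pig={fit.vc_.sigma2_pig:.0f}, "
      f"residual={fit.vc_.sigma2_res:.0f}, rho={fit.vc_.rho:.3f}")
print(f"ICC = {fit.icc_:.3f}")
ls = fit.lsmeans("hour").set_index("level")
for h in (1, 15):
    row = ls.loc[h]
    print(f"hour {h:2d}: LSMean = {row['estimate']:7.1f} cm/h "
          f"(95% CI {row['ci_lo']:.1f}-{row['ci_hi']:.1f})")
print(fit.type3().to_string(index=False))
```

prints

```
variance components: pig=13633, residual=39130, rho=0.197
ICC = 0.258
hour  1: LSMean =   651.3 cm/h (95% CI 590.1-712.5)
hour 15: LSMean =  1048.8 cm/h (95% CI 987.6-1110.0)
    effect  num_df  den_df          F            p  n_inestimable
       day      19    7185  11.518178 2.356970e-35              0
      hour      23    7185 121.147064 0.000000e+00              0
day x hour     437    7185   1.384040 4.409574e-07              0
```

One replicate of the study grid was simulated at pig-intercept variance
15,773, residual variance 38,884 and ρ = 0.19; the refit recovers ρ almost
exactly, while σ²_pig — estimated from only 16 pigs — is noisier, which is
why recovery is assessed as an average over replicates (see below). The
LSMeans reproduce the planted diurnal trough (01:00) and peak (15:00), and
the Type-3 tests recover the hour, day and day × hour structure.

The full pipeline (simulate → calibrate → movement → fit-lmm → fit-env →
report) is also available from the shell:

```bash
strawtrack run --seed 7 --out demo_out          # defaults: 16 pigs x 20 days
strawtrack fit-lmm --out demo_out --plot        # LSMean profile figures
```

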