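# riacd

Recurrence-interval analysis of extreme events in hourly monitoring series,
modelled with autoregressive conditional duration (ACD) models and their
spatial extension (SACD).

## The problem

Given hourly concentration series (air pollutants, an air-quality index, or
any positive hourly signal), how long until the next *extreme* episode?
`riacd` answers this in four steps:

1. **Diurnal adjustment.** Each hourly value is divided by the across-day
   average at the same hour of day,
   `x(t(d,h)) = c(t(d,h)) / [ (1/N_d) Σ_d c(t(d,h)) ]`,
   removing the 24-hour cycle and leaving a dimensionless series with
   per-hour-of-day day-mean exactly 1.
2. **Recurrence intervals.** For a threshold `q` (typically 2.0–4.0, i.e.
   2–4× the typical level), the waiting times between consecutive hours
   with `x > q` form the duration series
   `d_q = min{t − t′ : x(t) > q, x(t′) > q, t > t′}`.
3. **Conditional duration model.** Durations follow `d_s = ψ_s ε_s` with
   i.i.d. unit-mean positive innovations `ε` (exponential, or Weibull with
   shape `k ∈ (0,1]` and scale `λ = 1/Γ(1+1/k)`) and a GARCH-like recursion

   ```
   ψ_s = ω + Σ_u α_u d_{s−u} + Σ_v β_v ψ_{s−v} + Σ_j Σ_k γ_{jk} w_ij d^(ij)_{s−k}
   ```

   The γ-terms couple a station to its neighbours through *spatially
   reviewed* intervals `d^(ij)`: whenever station i's interval completes,
   the most recently completed interval at neighbour j (same threshold) is
   recorded.  With all γ = 0 this is the classic ACD(L_d, L_ψ) model;
   adding the nearest neighbour with one lag gives SACD(1,1,1).
4. **Estimation and forecasting.** Parameters are estimated by conditional
   maximum likelihood with Newey–West (Bartlett-kernel) standard errors,
   residuals are checked with the Ljung–Box Q(10) statistic, and the fitted
   recursion yields one-step and multi-step forecasts of the next waiting
   time, evaluated out of sample by AE = |ψ̂ − d| and RMSE over a holdout.

The package also ships the supporting analyses: the exceedance identity
`1/⟨d_q⟩ = P(x > q)` as a diagnostic, AR maximal-significant-lag and DFA
Hurst-exponent scans of the duration series, great-circle station geometry
with nearest-neighbour orderings, and a synthetic-data module (correlated
series pairs, exact ACD/SACD paths, diurnal cross-correlated station
networks) so the entire pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from riacd import (SACDParams, simulate_acd, fit, one_step_forecast,
                   rolling_out_of_sample, stationary_mean)

true = SACDParams(omega=0.1, alpha=[0.1], beta=[0.8])
d, _ = simulate_acd(true, n=2000, seed=42)       # exact ACD(1,1) path
f = fit(d)                                       # conditional MLE
for name, est, se, star in zip(f.param_names, f.theta, f.se, f.stars):
    print(f"{name:8s} {est:6.3f}  (se {se:.3f}) {star}")
print(f"Ljung-Box Q(10) = {f.qtest.Q:.2f}  (p = {f.qtest.p:.2f})")
print(f"implied stationary mean = {stationary_mean(f.params):.3f}")
print(f"next-interval forecast  = {one_step_forecast(f, d):.3f}")
recs, summ = rolling_out_of_sample(d[:500], holdout=30, mode="refit")
print(f"holdout RMSE = {summ.rmse:.2f}, avg AE = {summ.avg_ae:.2f}")
```

prints

```
omega     0.117  (se 0.026) ***
alpha_1   0.109  (se 0.015) ***
beta_1    0.777  (se 0.034) ***
Ljung-Box Q(10) = 11.54  (p = 0.32)
implied stationary mean = 1.032
next-interval forecast  = 0.705
holdout RMSE = 0.93, avg AE = 0.77
```

All three simulating parameters (0.1, 0.1, 0.8) are recovered within two
standard errors and flagged significant at the 1% level; the insignificant
Q(10) says the fitted recursion has captured the serial dependence of the
durations; the implied long-run mean ω̂/(1−α̂−β̂) ≈ 1.03 matches the
simulated process's stationary mean of 1; and the out-of-sample one-step
forecasts miss the realized waiting times by under one mean duration.

A full multi-station workflow (adjust → intervals → spatial review → fit →
forecast → report tables) is available from the shell:

```sh
riacd simulate network --stations 3 --days 200 net.csv reg.csv
riacd report --input-csv net.csv --registry-csv reg.csv --outdir out/
```

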