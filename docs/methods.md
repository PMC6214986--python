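# Methods

## Data model and diurnal adjustment

Hourly series are stored on a gap-free calendar-hour index; missing hours
are explicit NaNs.  The intraday cycle is removed by dividing each value by
the across-day mean at the same hour of day, the mean taken over days with
a present value at that hour.  A missing hour stays missing and can never
count as an exceedance — the alternative (imputing before thresholding)
would fabricate or suppress extreme events, which is worse than shortening
the effective sample.  An hour of day whose across-day average is zero
makes the division undefined and raises an error rather than producing
infinities.  Hours of day are taken from the timestamps as given; no
timezone conversion is attempted.

Station geometry uses the haversine great-circle distance on a sphere of
radius 6371 km.  Printed station coordinates are typically rounded to two
decimal degrees, which moves distances by up to ~1 km; comparisons against
published distance tables should therefore allow about 1%.  Neighbour
orderings sort by ascending distance with ties broken by ascending station
label, so results are deterministic.

## Recurrence intervals and spatial review

An exceedance is *strict* (`x > q`).  Durations are the integer-hour
differences between consecutive exceedance hours; the first exceedance
anchors the clock and contributes no duration.  Fewer than two exceedances
yields an empty, flagged result, not an error — high thresholds on short
series do this routinely and the caller decides what to skip.

The spatially reviewed interval pairs each completed interval at station i
(ending at hour t_s) with the neighbour's most recently *completed*
interval at an hour ≤ t_s.  The "at or before" convention is deliberate:
with it, two identical series review each other exactly, so the interval
correlation is 1 when the source correlation is 1.  Before the neighbour's
first completed interval the fill value is the neighbour's whole-series
mean duration, computed once.  A neighbour with no completed interval at
all has no mean to use; the pair is then filled with the base station's own
mean and flagged `all_fill` — downstream code treats such pairs as
uninformative rather than erroring out of a batch run.

Two temporal-structure scans are provided.  The AR scan fits a single
AR(max_lag) model (default max_lag 10) to the durations and reports the
largest lag whose coefficient passes a two-sided normal Wald test at the
given confidence; sequential order selection would be an alternative
reading, but the joint fit is the most direct one and is what the tests
calibrate.  Note that with 10 lags each tested at 5%, the probability that
*no* lag is flagged on independent data is 0.95¹⁰ ≈ 0.60, not 0.95 — the
scan is a descriptive screen, not a size-controlled joint test.  The Hurst
exponent uses first-order detrended fluctuation analysis with
logarithmically spaced windows from 8 to N/4, the standard estimator that
is robust to slow trends; it is written in-package because no DFA
implementation is available among the dependencies.

## The ACD/SACD model

Durations follow d_s = ψ_s ε_s with ε i.i.d. positive and unit-mean, and

ψ_s = ω + Σ_u α_u d_{s−u} + Σ_v β_v ψ_{s−v} + Σ_j Σ_k γ_{jk} w_ij d^(ij)_{s−k}.

All coefficients are non-negative and ω > 0, which keeps ψ positive.  The
spatial weights default to w = 1 for the selected neighbour(s) and 0
otherwise (the nearest-neighbour adjacency); an inverse-distance deterrence
can be supplied through the `weights` field but is off by default.

*Pre-sample convention.* All lagged quantities with index ≤ 0 — durations,
ψ values and reviewed durations — are set to the sample mean of the
duration series.  This is the standard ACD initialization; its influence
dies out geometrically at rate Σα+Σβ.

*Innovation laws.* Exponential, or Weibull with shape k ∈ (0, 1] and scale
λ = 1/Γ(1+1/k), which forces E[ε] = 1.  k = 1 is admissible and reproduces
the exponential exactly, so the exponential model is nested and the Weibull
fit can never have a worse likelihood.  Shapes above 1 would give a
hump-shaped duration density, contradicting the monotonically decreasing
histograms these interval series show, and are excluded.

*Stationary moments.* For the uncoupled (1,1) model the long-run mean is
μ = ω/(1−α−β).  For two mutually coupled (1,1,1) stations, taking
expectations of the two-line system and solving gives

E[d_i] = (ω_j γ_i + ω_i a_j) / (a_i a_j − γ_i γ_j),  a = 1 − α − β,

which reduces to μ_i when both γ vanish and to
μ_i + μ_j γ_i / a_i under one-way coupling.  The denominator must be
positive; otherwise a nonstationarity error is raised.

*Numerics.* The ψ recursion's autoregressive part runs through
`scipy.signal.lfilter` with initial conditions encoding the mean
pre-sample, giving C-speed evaluation that the tests verify against a naive
Python loop to 1e−12.  This matters because the rolling forecast refits the
model at every holdout origin.

## Likelihood and inference

The likelihood conditions on the first duration: contributions run over
s = 2..N with conditional density f(d_s/ψ_s)/ψ_s (exponential case:
log ψ_s + d_s/ψ_s).  The marginal law of d_1 is left unspecified, so the
first observation informs the recursion's state but not the likelihood —
standard conditional MLE.  The Weibull conditional density is the unit-mean
Weibull density of ε_s = d_s/ψ_s divided by ψ_s; this is the only form
consistent with d = ψε and E[ε] = 1.

Optimization is Nelder–Mead on transformed coordinates — log for ω,
logistic into (0,1) for α, β, γ and k — from a fixed default start
(ω = 0.1·mean(d), α = 0.1, β = 0.6, γ = 0.05, k = 0.8) plus seeded random
restarts (default 4; the replicate suites use 1 because the simulated
instances are well-identified and never need restart escapes).  No
summing constraint is imposed on α+β; nonstationary estimates are possible
and reported as-is.  Estimates within 1e−5 of a boundary are flagged
`boundary` rather than suppressed, since boundary β̂ = 0 entries are a real
feature of duration fits.

Standard errors are Newey–West sandwich estimates: the bread is the inverse
of a finite-difference Hessian of the negative log-likelihood, the meat a
Bartlett-weighted (1 − l/(B+1)) long-run covariance of per-observation
score vectors, with bandwidth B = floor(4(N/100)^(2/9)) by default and
exposed as a parameter.  Finite differences respect parameter bounds
(forward/backward steps at a boundary, e.g. k̂ = 1).  A singular Hessian is
ridge-regularized with a warning.  Significance stars use two-sided normal
quantiles at 10/5/1%.

One calibration caveat the tests document: when the data are fully
independent, α = 0 and β is unidentified (ω and β trade off along
ω/(1−β) = const), so Wald tests on β are not size-controlled under that
null.  The γ = 0 null keeps α and β identified, and the γ Wald test is
well calibrated (~5% spurious significance in simulation).

Residual adequacy uses the Ljung–Box portmanteau statistic
Q(L) = N(N+2) Σ_k ρ²(k)/(N−k) on the standardized innovations d/ψ̂, with
L = 10 by default, referred to a χ²(L) upper tail.

## Forecasting

The one-step forecast is the fitted conditional expectation
ψ̂_{N+1} = ω̂ + α̂ d_N + β̂ ψ̂_N (+ γ̂ d^(ij)_N): α̂ multiplies the last
*duration* and β̂ the last *conditional* duration, consistently with the
recursion.  Multi-step forecasts iterate the recursion substituting ψ̂ for
each unrealized duration — valid because E[d|I] = ψ — while reviewed
durations are held at their last observed value (their future evolution is
exogenous and unmodelled).  For α̂+β̂ < 1 and γ̂ = 0 the forecasts converge
geometrically to ω̂/(1−α̂−β̂).

The rolling out-of-sample test forecasts each of the last `holdout`
(default 30) intervals one step ahead.  Two modes: `refit` re-estimates on
all data strictly before each origin (expanding window), `fixed` estimates
once on the training part and rolls only the state.  Refitting is the more
faithful reading of a recursive scheme; the fixed mode exists because
refitting is ~30× the cost and the two give nearly identical errors on
stable series.  Non-convergent refits are flagged, excluded from averages
and counted — never silently imputed.  Errors are summarized as AE, RMSE
(square of d − ψ̂) and the breakpoint fractions p(AE < 1, 6, 12, 24, 48,
96 hours), which are non-decreasing in the breakpoint by construction.

## Synthetic data

The generators define the conditions under which the package is tested:

* **Correlated pairs** — two standard-normal series mixed to a target
  correlation c.  Thresholding at q = 2 and running the spatial-review
  scheme reproduces the characteristic curve: interval correlations stay
  below 0.1 for c ≤ 0.4, rise steeply beyond ~0.5, and reach exactly 1 at
  c = 1.  Defaults N = 10⁵ and 20 replicates.
* **Exact ACD/SACD paths** — d_s = ψ_s ε_s simulated forward from the
  stationary mean, 500 burn-in steps discarded.  Continuous durations by
  default, because the likelihood assumes continuous densities; an
  integer-hours mode (ceil, minimum 1) mimics empirical data for pipeline
  tests.  The coupled two-station simulation aligns the stations by event
  index s, exactly as the two-line recursion is written; coupling in
  calendar time would be an extension, not implemented.
* **Station networks** — hourly series built as a double-peaked 24-hour
  diurnal profile times unit-mean lognormal noise whose log-scale
  cross-station correlation matrix is configured (σ = 0.8 by default,
  giving the heavy right tail typical of concentration data).  What this
  generator does *not* emulate: meteorological regimes, seasonal cycles,
  instrument error and calendar-time event clustering across stations.
  Passing pipeline tests therefore demonstrate correctness of the
  machinery on realistic-looking input, not forecasting skill on real
  monitoring data.

All generators are bit-reproducible given (config, seed).

## Problem sizes and test design

The replicate suites use N = 2000 durations and 50 replicates for
parameter recovery and null-coupling calibration, N = 10⁵ for moment
checks and the correlation curve, and 500 replicates for the Ljung–Box
size check — sizes at which every calibrated rate is stable to a few
percentage points run-to-run.  Simulation-backed assertions use seeded
generators throughout, and each numerical routine is checked against an
independent oracle (naive loop recursions, product-form likelihoods,
spherical-law-of-cosines distances, textbook Ljung–Box, circulant-embedded
fractional Gaussian noise for the DFA estimator).

## Known limitations

* Exact reproduction of published real-data coefficient tables is out of
  scope: the underlying monitoring data are not publicly deposited.
* Generalized-Pareto innovations, logarithmic/Box–Cox ACD variants and
  probabilistic (interval) forecasts are not implemented.
* Likelihoods with many lags or many neighbours may fail to converge —
  an inherent feature of this model family; such fits raise or are flagged
  rather than returning bad optima.
* The spatial-review fill (the neighbour's whole-series mean) looks ahead
  when used in forecasting contexts before the neighbour's first interval;
  a training-window-only fill would be the conservative alternative and
  only affects the first few intervals of a series.
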