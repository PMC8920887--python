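# Methods

## Model

Uptake of an organic vapor into silicone is first-order in the difference
between the sampler's current load and its equilibrium load:

    N(t) = N_s-eq · (1 − e^(−k_e t)),     N_s-eq = C_a · V_s · K_sa

with three phases — kinetic (linear), curvilinear, equilibrium — depending on
how far k_e·t has progressed.  Inverting this relation gives the
air-equivalency equations used throughout: C_a = N / (V_s·K_sa·(1−e^(−k_e t))),
or equivalently with the sampling rate R_s = k_e·V_s·K_sa in the exponent.
All quantities assume constant exposure and standard indoor conditions;
"equivalency" flags that real deployments may differ.

Five inputs determine C_a: deployment time t, sampler volume V_s, amount N,
a rate parameter (k_e or R_s), and the partition coefficient K_sa.  K_sa
enters multiplicatively and is log-scaled, so its accuracy dominates the
accuracy of C_a.

## Curve fitting

Uptake curves are fitted either as the first-order exponential above or as a
rectangular hyperbola ("Michaelis–Menten shape", the conventional choice for
uptake curves in this literature; its plateau Vmax is read as N_s-eq and its
half-saturation time Km as the timescale).  The hyperbola is the default
form; the exponential is available because it is the generative model of the
equivalency equations and recovers its own parameters exactly on clean data.

Fitting is nonlinear least squares (scipy `curve_fit`, analytic Jacobians)
multi-started from a deterministic coarse grid over plateau guesses
(max amount × {1, 1.5, 3}) and timescale guesses (first half-rise time,
quarter-window, full window), keeping the lowest SSE.  The robust option
(default in the CLI) re-solves by iteratively reweighted least squares with
Tukey bisquare weights (tuning constant 4.685, MAD scale), warm-started from
the plain solution; it is deterministic and reduces — without eliminating —
the influence of single aberrant observations, which matters because outlier
removal from small chamber series is rarely justifiable.  On clean data the
robust and plain fits agree within 1 %.

Parameter SDs come from the Gauss–Newton covariance at the solution.  A
degenerate covariance yields NaN SDs; such estimates are ineligible for the
high-confidence filter downstream.  An optional square-root-of-time
transform is available for series that never approach equilibrium: the
chosen curve is fitted against √t, which stabilises the extrapolated plateau
for curvilinear data, and the result is never classified better than
CURVILINEAR because the plateau is then an extrapolation.

Equilibrium status is classified from the fitted fraction of N_s-eq reached
at the last timepoint: ≥ 0.9 EQUILIBRIUM, 0.5–0.9 CURVILINEAR, else
KINETIC_ONLY.  These thresholds are this package's convention for a
qualitative field notion.

Below-LOD observations are excluded from fits by default (the recorded
amount is the LOD bound, flagged).  Replicate series are pooled into one fit
as repeated measures by default; per-replicate fitting is an option.

## Derived parameters and uncertainty

- K_sa = (N_s-eq / V_s) / C_a, with V_s = mass/density.  Density defaults to
  1.10 g/mL (typical for PDMS wristbands; never stated with the samplers
  themselves), is configurable, and is recorded in every K_sa-bearing
  output because K_sa scales as 1/V_s.
- R_s: OLS slope (intercept fitted) of amount vs time over the kinetic
  window, divided by C_a, giving liters of air cleared per day.  The window
  defaults to observations where the fitted curve is below 25 % of N_s-eq
  (minimum 3 points); when the window is thinner the analytic initial slope
  of the fitted curve is used instead (N_s-eq·k_e or Vmax/Km) with no SD.
  Defining R_s as slope/C_a makes the exponent R_s·t/(V_s·K_sa)
  dimensionless.
- k_e = R_s / (V_s·K_sa); for first-order fits k_e is taken directly from
  the curve parameter and R_s derived from the identity instead.
- Uncertainty: first-order (delta-method) propagation with independence
  assumed — relative variances add for quotients; log10 transforms use
  sd_log = sd/(x·ln 10).  C_a and V_s are treated as exact.

## Partition models

log K_sa (or log k_e) is regressed on one physicochemical predictor:
boiling point from the TEST or OPERA QSAR systems (°C), log K_oa, or log
vapor pressure.  Weighted least squares with weights 1/y² reflects that
uncertainty grows as volatility falls.  Conventions chosen where the field
reports none:

- RMSE = √(Σ(y−ŷ)²/n) on unweighted residuals (common reporting; divisor n,
  not n−2).
- Adjusted R² = 1 − (1−R²)(n−1)/(n−2) from the weighted fit.
- Prediction intervals: t-distribution with n−2 df; variance of a new
  observation s²·(1/w₀ + 1/ΣW + (x₀−x̄_w)²/S_xx,w) with the new point's
  weight w₀ evaluated at the predicted value for 1/y²-weighted fits (its own
  y being unknown).  Simulated coverage at n = 30, level 0.95 falls in
  [0.93, 0.97].

The high-confidence-data (HCD) filter retains estimates with SD strictly
below 1 log unit — one log unit already spans an order of magnitude in
concentration — and sets aside, counted separately, estimates lacking an SD.

Repeated k-fold cross-validation (default 10 repeats × 10 folds) shuffles
with a seeded generator, splits into folds differing in size by at most one
(order-stratified only), and reports mean held-out R²/RMSE/MAE over all
resamples; held-out R² is computed against the fold's own mean and is NaN
for single-point folds (excluded from the mean).  The returned model's
coefficients always come from the full-data refit: CV estimates performance,
it does not average coefficients.  The seed is a required, logged input.

## Model registry and fallback

The three published cross-validated HCD models (see README) are hard-coded
in the registry.  No log k_e registry models ship: their published
regressions are shown only graphically and the coefficients are not printed,
so encoding them would mean fabricating numbers.  Rate handling is therefore
a policy: user-supplied per-chemical k_e values, or the
equilibrium assumption C_a = N/(V_s·K_sa) (default), which is exact once
k_e·t ≫ 1 and otherwise a lower bound — always accompanied by a warning, and
by a second warning when predicted log K_sa exceeds 6, where equilibrium is
unrealistic within a deployment and the air route itself loses relevancy.

The predictor fallback is exactly BP-TEST → BP-OPERA (switching to the
matching OPERA model), mirroring the recommended usage order; falling
further back to the log K_oa model requires explicit user action.

## Built-in chemical table

The packaged table holds the 22 chamber-calibration chemicals (14 VOCs,
8 SVOCs) with CAS (check-digit validated), molecular weight, experimental
and QSAR boiling points, log K_oa, vapor pressure at 25 °C, and chamber
exposure concentrations.  Missing cells are absent, never imputed.  Two
chemicals carry two exposure concentrations from repeated exposures, stored
as an ordered pair; for hexachlorobenzene the table value 0.590 ng/L is used
where a narrative mention of 0.508 ng/L also exists — the tabulated value is
treated as authoritative.

## Synthetic data

The chamber simulator draws amounts from the first-order generative model
with independent multiplicative lognormal noise of mean exactly 1 and chosen
CV (log-scale σ² = ln(1+CV²), μ = −σ²/2) — measurement error in
chromatographic quantitation is strictly positive and roughly proportional.
Defaults mirror the calibration design: 6 log-spaced timepoints over
0.25–14 days (dense early, since volatile compounds equilibrate within
hours), 3 replicate series, seeded and bit-reproducible.  Amounts below the
LOD are recorded at the bound and flagged.

What the simulator does **not** emulate: drift in chamber concentration,
dry-deposition bias in SVOC delivery (a suspected cause of low apparent
exposure for the heaviest compounds), inter-sampler mass variation,
correlated errors within an analytical batch, and any temperature/humidity/
wind dependence.  Passing recovery tests therefore demonstrates correctness
of the estimators under the stated error model, not robustness to every
artifact of real chamber data.

Problem sizes used in the test suite and acceptance checks — 200 simulated
series for kinetic recovery, 500 replications for calibration-slope
recovery, 10⁶ draws for the Monte-Carlo propagation oracle, 2000
replications for interval coverage — were chosen to make sampling noise in
the checked statistics small relative to their tolerances.

## Known limitations

- K_sa and k_e are not adjusted for temperature, humidity, or wind; the
  models assume the standard indoor conditions of the calibration.
- The equilibrium-assumption default underestimates C_a for compounds still
  in the kinetic phase; supplying k_e values is strongly preferable for
  SVOCs.
- Dermal/direct-contact uptake is outside the model; for high-K_sa
  compounds the air-equivalent number may not describe the dominant exposure
  route.
- The kinetic-window fraction (25 %) and equilibrium thresholds (0.9/0.5)
  are conventions; results near a boundary should be inspected.
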