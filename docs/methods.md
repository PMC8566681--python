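# Methods

## The measurement being modelled

An accelerated oxidation reactor holds ~5 g of oil in a sealed titanium
chamber at a set temperature (instrument range 50–110 °C) under an initial
oxygen pressure of 600–800 kPa and records the headspace pressure over
time. Oxygen uptake is slow until the oil's antioxidant capacity is
exhausted, then autoxidation propagates and the pressure falls rapidly.
The induction period (IP) — the industry's oxidative-stability summary —
is defined by the two-tangent construction: the time coordinate of the
intersection between a tangent to the slow baseline decay and the tangent
at the steepest point of the consumption drop.

## Synthetic curve model

Instrument vendors do not publish raw curves, so the generator defines its
own functional form with the qualitative features that matter to the
detector — a near-linear baseline, a smooth accelerating drop, and additive
sensor noise:

    P(t) = p0 − m1·t − d / (1 + exp(−s·(t − t_c))) + ε,   ε ~ N(0, σ²)

| parameter | meaning | default | rationale |
|---|---|---|---|
| `p0` | initial pressure, kPa | 800 | upper setting of real instruments |
| `m1` | baseline slope, kPa/h | 0.5 | slow pre-oxidation uptake |
| `d` | consumption depth, kPa | 200 | a clearly resolved drop |
| `s` | logistic steepness, 1/h | 1.0 | onset sharp relative to the record |
| `t_c` | logistic centre, h | 36.6 | places the IP near a real 70 °C run |
| `dt` | sampling interval, h | 0.05 | dense sampling, 3-min cadence |
| `noise_sd` | sensor noise, kPa | 0.5 | ≈0.06% of p0; keeps detection error below the 0.01 h print precision of IP tables |

For this family the two-tangent IP has the closed form **IP = t_c − 2/s**,
independent of `d` and `m1`: the tangent at the logistic inflection has
slope −m1 − d·s/4 and sits d/2 below the baseline line, so the tangents
meet 2/s before the centre. That exact ground truth is what makes the
detector testable. `simulate_temperature_series` inverts the relation
(`t_c = 10^(log_ip0 − k0·T) + 2/s`) so a whole temperature series follows a
prescribed kinetic law exactly; records extend to 1.6 × t_c. All noise is
drawn from `numpy` generators seeded per curve (`template.seed + index`),
so identical inputs reproduce identical curves bit for bit.

What the generator does *not* emulate: heteroscedastic or drifting sensor
noise, chamber thermal transients at the start of a run, the empirical
dependence of IP on oxygen pressure (real IPs shorten measurably from 600
to 800 kPa; `p0` is cosmetic here), and sample-mass effects (negligible in
practice). Passing tests therefore demonstrate correctness of the
*numerics* — detection geometry, fitting, extrapolation — not robustness to
every instrument artefact.

## Two-tangent detection

Smoothing and differentiation use moving local-linear least-squares fits
(Savitzky–Golay, polynomial order 1), not raw finite differences, to
tolerate kPa-level noise; the default window is max(5 samples, 0.5 h/dt),
odd. The steepest-descent sample is the minimum of the smoothed
derivative, ties broken toward the earliest time so detection is
deterministic. The oxidation tangent is a least-squares line over
±`tangent_halfwidth` samples around that point; the default is
max(5, 1% of samples) but capped at ±0.25 h — on long records a wider
window averages over the curvature of the consumption sigmoid, flattens
the fitted tangent and biases the IP low by ~0.2 h. The baseline tangent
is fitted over the 5–50% span of the elapsed time up to the steepest point
(the first 5% is skipped to avoid equilibration transients; the span is
measured from the record start, which makes detection equivariant under
time shifts and invariant under pressure offsets). Tangents closer in
slope than `min_slope_separation` (1 kPa/h) mean no detectable onset.

With these defaults, on noiseless simulated curves the detected IP is
within 0.2% of the closed form (within 1% for any s ≥ 0.5 at dt = 0.05 h),
and over 200 seeded noisy replicates at the default noise the median
relative error is ~0.1% with a maximum of ~0.3%.

Real instruments cap runs (240 h is a common limit); when a
`censor_limit` is configured, a record that reaches it without a
detectable onset yields a *flagged* censored measurement holding the limit
as a lower bound, never a silent drop. Censored measurements are excluded
from kinetic fits with a warning.

## Kinetics and shelf-life

The temperature law is `log10 IP = Log IP0 − k0·T` with T in °C — the
OSI-field convention (called "Arrhenius" there despite not using
reciprocal kelvin), base-10 throughout. Fitting is ordinary least squares
on ≥3 distinct temperatures; R² is the squared Pearson correlation
(identical to the regression R² for a simple line). Parameters are
reported at 4 decimals, the precision at which such fits are published;
extrapolation uses these reported values so that derived tables are
reproducible from what is printed.

Shelf-life at ambient temperature: `ip_hours = 10^(Log IP0 − k0·T)`,
rounded to the nearest whole hour, divided by 24, rounded to whole days
(halves away from zero). The whole-hour pre-rounding is deliberate: it is
the convention under which published shelf-life tables reproduce exactly
from their published kinetic parameters (direct division differs by one
day in borderline cases, e.g. 13 523.8 h → 563.49 days vs the published
564). Only downward extrapolation is permitted — the law is a calibration
over the fitted range, and evaluating it above the lowest fitted
temperature would be interpolation the instrument should do instead.

## Correlation screen and grouped regression

Pearson r with the classical two-tailed t significance (n−2 df) screens
shelf-life against label-available properties over the nine reference
oils (pumpkin seed oil is excluded throughout: its chlorophyll load
confounds shelf-life). The one censored accelerated run (peanut at 70 °C)
enters the log-IP screen via its fitted law's extrapolated value — the
reading that reproduces the published correlations exactly — and is
flagged as such in the reproduction report.

The prediction models regress shelf-life on a composition predictor X1
(SFA%, UFA%, SFA/UFA or PUFA%) plus the binary family indicator X2, by OLS
with intercept (statsmodels). The overall significance is the F-test on
(2, n−3) degrees of freedom — this reproduces the published p-values,
identifying the (unstated) test used. Multiple r is √R². X2 is *data*,
shipped with the reference tables: the two families correspond to
different tocopherol profiles, which the package does not attempt to infer
from composition. A constant response returns multiple_r = 0, p = 1
rather than a 0/0. Predictions outside the calibrated range (negative
days) are returned with a warning, never clamped silently.

## Known reproduction caveats

`reproduce-paper` recomputes 149 published cells and matches 146 at print
precision. The three annotated exceptions, kept visible rather than
patched: the two acid-value correlation cells (the source evidently
correlated unrounded replicate means, which printed values cannot
recover) and one regression coefficient whose published rounding is off
by one unit in the last digit (computed 599.3 printed as 600).

## Problem sizes

Simulation-based tests use single curves of ~1 200–2 800 samples
(dt = 0.05 h over records of 55–140 h), 200-replicate Monte-Carlo runs for
the detector's error distribution, and three-temperature series for
pipeline round-trips; the whole suite, reproduction workflow included,
runs in a few seconds on one CPU.
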