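# Methods

## Model

A growth reference summarizes the age-varying distribution of a measurement
by three curves (Cole's LMS method): L(t), the Box-Cox power that normalizes
skewness; M(t), the median; and S(t), the scale. Given a measurement X at
decimal age t, the z-score is

- identity mode (parameters tabulated with L = 1 throughout: height, head
  circumference, sitting height, leg length, arm span, relative sitting
  height, foot length): `Z = (X − M)/S`, with S an **absolute standard
  deviation** in measurement units;
- Box-Cox mode (weight, BMI): `Z = ((X/M)^L − 1)/(L·S)`, with S a
  **coefficient of variation**; for |L| < `L_EPS = 1e-7` the analytic limit
  `ln(X/M)/S` is used to avoid catastrophic cancellation (the relative error
  of the limit is O(L), so both branches agree to ~1e-7 at the switch).

Two S conventions therefore coexist in one bundle, mirroring source tables
that print an SD column for the L = 1 parameters and a CV for the skewed
ones. Because a bundle cannot declare its convention, the validator emits an
advisory warning (`s-convention`) when an identity-mode node has S < 0.5
while M > 20 — the signature of a CV supplied where an SD is expected.

Percentiles are 100·Φ(Z) (scipy's normal CDF); the inverse quantile uses
Φ⁻¹. The inverse transform, used for centile curves and synthetic cohorts,
is `X = M + Z·S` (identity) or `X = M·(1 + L·S·Z)^(1/L)` (Box-Cox,
`M·e^(S·Z)` in the L → 0 limit). The Box-Cox inverse is undefined when
1 + L·S·Z ≤ 0; this is a genuine saturation of Cole's transform (e.g. very
high BMI z with strongly negative L), reported as an `InvertibilityError`
rather than clamped.

## Age interpolation

References tabulate (L, M, S) on a grid: every 6 months from birth to age 4,
then annually to 20, for the birth-to-20 parameters (25 nodes; the age-4
node belongs to both interval regimes and appears once); annually over 2–20 y
for the proportion parameters and 3–20 y for foot length. Off-grid ages get
**component-wise piecewise-linear interpolation** of L, M and S, chosen as
the simplest scheme that is exact at nodes, bounded by the bracketing
values, and monotone between nodes; users comparing against cubic schemes
know exactly what was done. Coefficients are interpolated, not z-scores —
the conventional LMS practice. The age domain is a closed interval; ages
outside it raise an error with the valid range (no extrapolation, no
clamping, since a silently clamped age hides a clinically meaningful
out-of-range query). When birth and visit dates are given instead of an age,
decimal age = days between / 365.25.

## Parameters and defaults

| parameter | units | age domain (y) | mode |
|---|---|---|---|
| height, head_circumference | cm | 0–20 | identity |
| weight | kg | 0–20 | boxcox |
| bmi | kg/m² | 0–20 | boxcox |
| sitting_height, leg_length, arm_span | cm | 2–20 | identity |
| relative_sitting_height | % | 2–20 | identity |
| foot_length | cm | 3–20 | identity |

Derivations (only when the target is absent; measured values always win):
BMI = weight/(height/100)²; leg length = height − sitting height; relative
sitting height = 100·sitting height/height. Derived rows carry the
`derived_input` flag. `extreme_percentile` flags |z| > 3 — an informational
convention marking chart-boundary territory, not a validity cutoff.
Percentiles are computed at full floating precision; the CLI displays 1
decimal for percentiles and 2 for z (clinical chart-reading granularity,
configurable via the config file).

## Synthetic fixtures

The generator emulates the *structure* of published European achondroplasia
references, never their values. Median trajectories follow
`M(t) = M0 + (M1 − M0)·(1 − (1 − u)^c)` with u the age normalized to the
domain, which front-loads infant growth; endpoints loosely reflect
achondroplasia anthropometry (adult median height ≈ 131/124 cm male/female,
relatively large head, short limbs, high relative sitting height declining
with age). S and L vary linearly across the grid. A seeded ±2% jitter on the
endpoint controls makes distinct seeds produce distinct, always-valid
bundles; the generator is a pure function of its seed. Box-Cox shape
controls are constrained to max |L·S| < 1/4.2 so that the |z| = 4 extreme
items injected into cohorts remain inside the transform's support.

Synthetic cohorts stratify ages (even-indexed patients on grid nodes,
odd-indexed strictly between nodes, so interpolation is always exercised),
alternate sexes, include every parameter whose domain contains the patient's
age, and synthesize values through the inverse transform so the generating z
is exact ground truth. With the standard-normal z distribution, one +4 and
one −4 item per parameter are injected; with a fixed z₀ the cohort is left
homogeneous so that e.g. z₀ = 0 cohorts sit exactly on the median curve.

What passing tests on these fixtures do show: the engine's lookup,
interpolation, transforms and inversions are mutually consistent and agree
with an independent re-derivation to 1e-9. What they do not show: anything
about the correctness of real coefficient tables, measurement error, or
non-linear between-node behaviour of real references (real L/M/S curves are
cubic-spline-smooth; linear interpolation of a real table is an approximation
the original charts share).

## Agreement check and the gold standard

The agreement rate is the percentage of (patient, parameter) evaluations in
which the engine and a manual oracle agree within 1e-9 on z. The oracle
(`agrowth._oracle`) is a deliberately separate code path — stdlib only, no
imports from the engine module — that re-enacts the clinician's manual
procedure: scan the flattened table for bracketing rows, interpolate L, M, S
by hand, evaluate the printed formula. The gold standard here is this
independent re-derivation (a developer-operated copy of the tool itself
would be circular). 100% agreement is therefore evidence of correctness, not
a tautology; `scripts/acceptance.py` recomputes it on a 30-patient cohort
(about 250–270 evaluations, since patients younger than 2–3 y lack the
proportion and foot-length parameters).

## Simulated reliability study

The inter-rater harness schedules, per rater, 9 parameters × 3 cases × 2
methods = 54 calculations. Human chart-reading error is modelled as zero-mean
normal noise on z with SD 0.2 (a documented stand-in chosen to put the
pooled manual median deviation in the ~0.13–0.17 range typical of manual
chart reading; recorded deviations are then half-normal with median
0.6745·SD ≈ 0.135). The automated method reproduces the gold standard by
construction, so its deviations are identically zero. This is a synthetic
error model, not a reproduction of human rater data. Deviation summaries are
median [IQR] with the SPSS/Weibull type-6 quantile estimator (h = (n+1)p,
linear between order statistics) — the convention under which three samples
{0.07, 0.17, 0.30} summarize to 0.17 [0.07–0.30]. Manual-vs-automated
significance in the CLI report is a scipy Mann-Whitney U call.

## Numerical choices and edge cases

- Duplicate (parameter, sex, age) rows in a bundle are an error, never
  averaged; node order must come from the file (a descending file is an
  ordering violation, not silently repaired).
- Floats are serialized with `repr`, so write → load round trips are exact
  and batch outputs re-evaluate to bit-identical z.
- Malformed patient rows are isolated with their line number; one bad line
  never aborts a batch. Duplicate (patient, age, parameter) rows keep the
  first value and record the rest as malformed.
- Centile grids extending beyond the reference domain are truncated with a
  warning (the only place truncation occurs).
- Problem sizes: the test suite and acceptance script use 30-patient
  cohorts, 18-curve bundles, and a 5 400-sample rater simulation for the
  half-normal convergence check — desk-scale runs that complete in seconds.

## Known limitations

- Linear L/M/S interpolation differs from the cubic smoothing used to fit
  real references; at the 6-month/annual grid spacing the discrepancy is
  small but nonzero between nodes.
- No growth-velocity or treatment-response computation, no EHR integration,
  no fitting of L/M/S curves from raw data.
- The identity-mode SD convention is asserted, not auto-detected; bundles
  whose L = 1 parameters tabulate CVs must be converted (the validator's
  warning is a heuristic, not a guarantee).
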