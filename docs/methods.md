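# Methods

## The estimator

esCCO treats stroke volume as an affine function of pulse wave transit
time, SV = K·(α·PWTT + β) with α < 0, and cardiac output as CO = SV·HR/1000.
PWTT — the interval from the ECG R wave to the peripheral pulse-oximetry
wave arrival — is the sum of the pre-ejection period and the arterial pulse
travel time; both lengthen as stroke volume falls, which motivates the
negative slope. The package consumes event timestamps or period-averaged
PWTT, never raw waveforms; when beat events are supplied, a trailing moving
average (default 8 beats) reduces the beat stream to the monitor's
period-measurement convention.

α and β set the physiological scale of the relation and are configurable
everywhere, with defaults α = −0.5 ml/ms and β = 150 ml chosen so SV spans
roughly 10–120 ml over PWTT 60–280 ms. They are free constants of the
implementation, not estimated quantities; every fit and test passes them
explicitly. K is dimensionless and fixed per patient at calibration:
K = ref_CO·1000 / (HR·(α·PWTT+β)), so the estimate reproduces the reference
exactly at the calibration point. The estimate is rejected (flag
`NONPHYSIOLOGIC_SV`) when α·PWTT + β ≤ 0.

## Patient-information calibration

The non-invasive calibration predicts the reference CO by ordinary least
squares on seven predictors: age, sex (indicator M=1/F=0), height, weight,
pulse pressure, heart rate and PWTT, plus an intercept. Design choices:

- predictors enter untransformed, with no interactions;
- "blood pressure" enters as pulse pressure (systolic − diastolic), the
  pressure summary mechanistically linked to stroke volume and transit
  time; this is configurable at the call site by passing a different value;
- body surface area (Du Bois: 0.007184·h^0.725·w^0.425) is available as a
  derived covariate but excluded by default, since height and weight
  already enter;
- fitted coefficients are data — serialized to/loaded from JSON — never
  constants of the package.

The fit uses statsmodels OLS; rank deficiency raises an error naming the
collinear predictors. Standard errors support the interval-coverage checks
in the tests. The training design in which each patient contributes the
rows with their maximum and minimum reference CO is supported naturally
(rows are the unit of fit) and exercised by `fit_calibration_from_cohort`.

## Automated exclusion

Rules evaluate independently and their flags are a set union, so the pass
is order-independent and monotone (adding a rule can only grow a flag set).
A sample is excluded iff its flag set is non-empty.

- **Context**: CPB, aortic cross-clamp, OPCAB posterior-wall tags map to
  exclusion flags (non-pulsatile or distorted signal periods); pacing is a
  recognized annotation but not an exclusion rule.
- **R-wave plausibility**: a beat is flagged when its RR interval deviates
  from the centred running median (window 9 beats) by more than 40 %.
  A halved interval is a double-detection, a doubled one a missed beat;
  physiological jitter of a few percent never approaches the threshold.
- **SV–PWTT consistency**: relative changes of SV and PWTT that are
  concordant in sign and both exceed 15 % are unreachable under one
  calibration of the negative-slope relation and are flagged (the cardiac
  tamponade pattern — SV 39.7→13.6 ml with PWTT 199→157 ms — triggers this
  rule). Because the device's independent SV channel (pulse-contour
  analysis) is out of scope, the pipeline uses pulse pressure as the SV
  surrogate: the rule compares relative changes only, so the
  SV↔pulse-pressure proportionality cancels. Each sample is compared
  against the most recent sample of the same subject *not* flagged by this
  rule; a transient artifact is therefore flagged once at onset and the
  recovery back to the retained baseline is not penalized.
- **Triplicate acceptance**: a thermodilution measurement is accepted iff
  every bolus lies within ±10 % of the triplicate mean, boundary inclusive
  (a deviation of exactly 10 % is acceptable).
- Heart rate (30–180 /min) and pulse pressure (10–120 mmHg) gates are soft:
  out-of-range values produce warnings, not exclusions, since no
  quantitative rule is established for them.

All thresholds are fields of `QcThresholds`; the defaults above are
declared free parameters — the rule structure is the contract.

## Agreement and trending statistics

- **Bland–Altman**: bias is the mean of test−reference differences; the SD
  uses the sample convention (n−1); limits of agreement are bias ± 1.96·SD.
- **Repeated-measures correction**: with several pairs per subject the
  pooled SD understates the population spread. The differences are
  decomposed by one-way random effects (method of moments on the ANOVA mean
  squares with the unbalanced-design weight n₀); the corrected variance is
  the sum of the between- and within-subject components, the between
  component truncated at zero. With one pair per subject the corrected SD
  equals the plain SD; with a single subject the plain SD is returned with
  a warning.
- **Percentage error**: 2·SD/mean(reference)·100, with ≤ 30 % the
  conventional interchangeability bound.
- **Polar trend analysis**: successive within-subject CO changes
  (current − previous, never across subjects) map to polar coordinates —
  radius (d_ref+d_test)/2, angle atan2(d_test, d_ref) − 45° measured from
  the identity line. Pairs with negative mean change are reflected through
  the origin (half-circle transform), placing all angles in (−90°, 90°].
  Pairs with mean change below the 0.5 L/min central zone are excluded as
  uninformative; the boundary 0.5 is included. A (0, 0) change pair has no
  defined direction and falls in the central zone by construction. Radial
  limits default to bias ± 1.96·SD of the included angles, with an
  empirical 2.5/97.5-percentile option. Concordance counts |angle| ≤ 30°,
  boundary inclusive — declared and tested.

## Synthetic cohorts

The generator emulates a perioperative validation study, not raw
physiology:

- demographics: normal draws with mean ± SD 65.3 ± 12.6 y, 159.9 ± 10.3 cm,
  59.1 ± 12.5 kg, two-thirds male, clipped to sane ranges;
- true CO: a reflected Gaussian random walk (innovation SD 0.7 L/min per
  measurement interval) inside 1.3–15.5 L/min, started at a
  demographics-dependent baseline whose generating coefficients are kept in
  the truth record — the simplest dynamics with controllable trend
  magnitude for exercising the polar statistics;
- heart rate: log-normal around 75 /min (σ_log 0.15), bounded 40–140;
  stroke volume CO·1000/HR is clamped to 25–110 ml with HR adjusted, which
  keeps the inverse transit-time map in a physiological 80–270 ms band;
- PWTT: the exact inverse (SV/K − β)/α at the subject's true K (clipped to
  1.0–1.4) plus Gaussian noise (default 4 ms);
- pulse pressure: 0.5 mmHg per ml of stroke volume over a normal diastolic
  pressure — a deliberately crude windkessel surrogate that gives the
  SV–PWTT consistency rule an SV channel;
- thermodilution: each bolus is true CO·(1+ε), ε ~ N(0, 5 %) —
  proportional (CV-type) noise, since thermodilution error scales with
  flow;
- artifacts: transient tamponade-like events (SV ×0.35, PWTT ×0.8 relative
  to the previous sample, pulse pressure and thermodilution regenerated
  consistently), CPB context windows, and isolated halved/doubled RR
  intervals, at per-sample rates 1 %, 5 % and 2 %, with exact labels.

Default cohort size is 181 subjects × 3 measurement pairs, the scale of a
multicentre validation set; all tests and the acceptance script run in
seconds at these sizes. What the generator does **not** model: waveform
morphology, pre-ejection-period dynamics, vasoactive-drug and SVR effects
on pulse wave velocity, arrhythmia, and any systematic disagreement between
the esCCO model and the circulation. Passing end-to-end checks therefore
demonstrate the correctness and internal consistency of the estimator and
statistics — not the clinical accuracy of PWTT-based CO, which on real data
is limited by exactly the effects excluded here.

## Numerical choices and degenerate inputs

- Triplicate and concordance boundaries are inclusive with a 1e−12 relative
  guard against floating-point representation.
- Bland–Altman requires n ≥ 2; correlation is NaN when either method is
  constant; polar analysis with every pair central-zone-excluded returns a
  result flagged `undefined` with NaN statistics rather than raising.
- JSON reports round to 6 significant digits and contain no wall-clock
  timestamps, so identical seeds give byte-identical reports; CSV exports
  keep full precision and round-trip exactly (round-trip float parsing on
  read).
- Calibration at a sample where α·PWTT + β ≤ 0 raises; prediction from an
  unfitted patient-information model raises; predictors outside the fitted
  range warn but evaluate.

## Known limitations

- The SV–PWTT consistency rule sees pulse pressure, not a true independent
  SV measurement; its sensitivity on real data depends on the
  pulse-contour channel it stands in for.
- The patient-information calibration is a plain OLS on seven predictors;
  no shrinkage, selection or nonlinearity, by design.
- The repeated-measures correction assumes exchangeable within-subject
  differences (no serial correlation within subject).
- Confidence intervals on the polar statistics and four-quadrant
  concordance are out of scope.
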