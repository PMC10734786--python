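# Methods

## The tolerable-error model

Per-participant device error is defined as the mean of three paired
test-minus-reference PWV differences. Across participants these means are
modelled as D ~ Normal(μ, σ²). The accuracy criterion asks for the bound E
with P(|D| ≤ E) = 0.85, i.e. the solution of

    Φ((E − μ)/σ) − Φ((−E − μ)/σ) = 0.85,

which `error_at_probability` finds by bracketing bisection on
[0, |μ| + 10σ] to 1e−6 m/s (guaranteed convergence, no derivatives; the
left-hand side is strictly increasing in E). The bound is symmetric in the
sign of μ, strictly increasing in both |μ| and σ, and degenerates to |μ| as
σ → 0. `max_sd_for_error` inverts the map in σ, again by bisection, using
the fact that E(σ) is strictly increasing; the two functions are
inverse-consistent to 1e−5 m/s (checked in the test suite).

Grading conventions: |μ| and σ are first rounded **up** to 0.05 m/s
(conservative table lookup; applying the rounding to the absolute mean
keeps the criterion two-sided and sign-symmetric). The grade uses the
unrounded bound against the thresholds 1.0 m/s (good) and 1.5 m/s
(acceptable). The *displayed* bound is rounded up to 0.01 m/s: with inputs
(0.40, 0.45) the exact bound is 0.8710 m/s and is reported as 0.88 m/s.
Round-up display is deliberate — plain rounding would report 0.87 and
understate the error — and is consistent with the conservative input
rounding. Alongside the model-based grade, reports carry the empirical
fraction of participants within 1.0 m/s as a supplementary statistic; the
normal-model grade is primary.

## Sample-size calculus

The probability of tolerable error is estimated from a binomial sample, so
precision is governed by the normal-approximation (Wald) half-width
100·z₍(1+c)/2₎·√(p(1−p)/n) percentage points. At n = 85, p = 0.85,
c = 0.90 this is 6.37 pp, giving the assured lower bound
85 − 6.37 = 78.63%. The Wald form is the default because it reproduces the
protocol's printed ±7% / ≥78% pair exactly; a Wilson half-width is
available via `method="wilson"` for users who prefer a boundary-respecting
interval.

## Pairing and agreement statistics

Simultaneous sessions pair T_i with R_i (i = 1..3). Sequential sessions
compare each T_i with the mean of the two reference readings closest in
time among R1..R4; under the canonical interleaving R1 T1 R2 T2 R3 T3 R4
this yields mean(R1,R2), mean(R2,R3), mean(R3,R4). Distance ties (a test
reading exactly mid-way) are resolved by a stable sort on (distance,
timestamp), which selects both flanking readings — the deterministic
behaviour the canonical order requires. The interleaving itself is
timestamp-driven, so permuted input order gives identical results.

Cohort statistics are computed over participant mean differences (the
protocol's unit of error): sample SD with the n−1 denominator throughout —
including the two-measurement CV, where SD = |m1 − m2|/√2 — and limits of
agreement at mean ± 2·SD exactly (not 1.96·SD), as the reporting
requirements prescribe. The Bland-Altman regression fits difference on
per-participant average PWV by OLS; participant means (not all three pairs)
are used so the regression matches the error definition. The slope's
p-value is the standard two-sided t test. Differences are oriented
test − reference. Test-retest precision uses the same Bland-Altman
machinery with a predefined clinical agreement limit, default 1.0 m/s.

## Screening rules

Age bands are half-open: [18,30), [30,50), [50,70), [70,∞), matching the
integer labels <30, 30–49, 50–69, ≥70. "Relatively even spread" across
bands is enforced only through the explicit ≥10-per-band rule; an evenness
ratio (min/max band count) is reported but never fails a cohort, since no
numeric evenness criterion exists. The acute vasoactive-medication window
defaults to 24 h (configurable; the protocol names the window without a
number, and 24 h covers common long-acting agents). Hemodynamic stability
is strict: a change of exactly 5% in HR, SBP or DBP fails. BMI ≥ 40 kg/m²
is exclusionary with an inclusive boundary. The reference-PWV distribution
quotas are applied to participant-level mean reference PWV by default (the
analysis unit); reading-level application is a one-line change at the call
site since the checker only sees numbers.

## Waveform processing

The intersecting-tangent foot is the intersection of the tangent through
the maximum-upstroke-slope point with the horizontal line through the
preceding diastolic minimum. Both landmarks are localised on a cubic-spline
interpolation of the samples evaluated at the requested resolution
(default 1 ms); beats are segmented by systolic-peak detection (prominence
≥ 40–50% of the signal range, minimum spacing 0.6 of the median peak
interval). Passing `resolution=None` disables interpolation and snaps the
foot to the nearest sample — provided purely to quantify the quantization
error that subsample detection removes (at 120 Hz: ~2.4 ms mean error
versus ~0.01 ms interpolated, on noiseless synthetic beats).

Diastole patching fits a quadratic to the late-diastolic segment (an
80 ms window ending just past the diastolic minimum) and a straight line
to the 20–80% portion of the upstroke, and intersects them, taking the
root nearest the minimum. The published description of this method names
it without fixing details; this variant is validated against the package's
own fixtures (agreement with the intersecting tangent within 5 ms on clean
beats) and is not claimed equivalent to any specific prior implementation.
Ill-conditioned fits are recorded as per-beat failures, never silently
skipped.

Transit times pair proximal and distal feet by nearest-onset matching
within half the median proximal foot-to-foot interval, require strictly
positive per-beat delays and at least 10 matched beats, and report
PWV = effective length / mean(Δt), displayed to 0.1 m/s. Path lengths:
subtraction (notch→femoral − notch→carotid) or 80% of the direct
carotid-femoral distance.

### Synthetic waveforms and ground truth

The generator builds a pressure-like beat (half-cosine upstroke, systolic
decay, dicrotic bump, exponential diastolic runoff) and band-limits it to
20 harmonics via its Fourier series, which also enforces the Nyquist
check at synthesis time. Ground-truth feet are defined as the
intersecting-tangent foot of the *continuous* band-limited template,
located once on a 10 µs grid; per-beat truths follow by periodicity and
are exact regardless of the sampling rate the detector is given. The foot
sits a quarter-period into the record so every beat has a usable preceding
diastole. Noise is additive white Gaussian, scaled to the pulse amplitude.
These waveforms have no respiratory modulation, baseline wander,
heart-rate variability or reflected-wave variation, so detector accuracy
on them bounds only quantization and algorithmic error, not robustness to
real hemodynamic artefacts.

## The study simulator

`SimulationConfig` defaults define the canonical study: 85 participants,
even age-band weights, balanced sexes, true PWV = 4.0 + 0.85·(age/10) m/s
with 0.9 m/s between-subject SD floored at 3 m/s (fixture coefficients
chosen to span the composition quotas, not physiological claims), constant
device bias 0.36 m/s, per-participant device offset SD 0.409 m/s and
0.2 m/s per-reading noise on both devices. In sequential mode the
participant-mean-difference SD implied by these is
√(0.409² + 0.2²/3 + 10·0.2²/36) ≈ 0.44 m/s, so a default study sits at
the worked grading example's operating point. Noise is Gaussian and
homoscedastic (matching the normative model); a proportional-bias term
exercises the Bland-Altman regression. Readings are recorded to 0.01 m/s.
All stages are reproducible under the config seed.

`quota_satisfying_cohort` allocates participants deterministically (bands
as even as possible, alternating sexes, PWV tranches at 5.5 / 7.0 / 8.5 /
10.5 m/s sized to the 5% / 20% / 5% quotas with low values in the youngest
band and high in the oldest) and is the canonical passing fixture for the
composition checker and the pipeline-conservation tests.

Simulation sizes used by the test suite — 200 studies of n = 85 for
parameter recovery, 10⁶ draws per cell on a 20-cell grid for the
Monte-Carlo mass check, eight 12-beat records for the quantization study —
were chosen so that Monte-Carlo error is comfortably below each asserted
tolerance.

## Reporting

`run_validation` refuses to run without pre-declared quality criteria
(the protocol requires failure criteria to be stated in advance). The
pipeline discards ineligible participants and hemodynamically unstable
sequential sessions with per-participant reasons; discarded plus analysed
counts always equal the input count. The checklist items are reconstructed
from the reporting requirements (measurement principle, fiducial point and
detection method, training/validation separation, version strings, data
availability, stratified analyses, before/after hemodynamics, discard
accounting); the full supplementary checklist wording is not reproduced
here, so items are extensible. Reports are emitted as JSON (first-class,
for public deposition) and Markdown; every number in them is recomputed
from the input data by the library API.

## Known limitations

- The normative model is strictly Gaussian; no distribution-free grading
  is offered as a primary criterion, and no Bayesian reformulation.
- Agreement analysis is simple Bland-Altman on participant means — no
  repeated-measures or mixed-model variants.
- The waveform engine does not model invasive-catheter dynamics, ECG
  gating, or second-derivative foot methods (the latter are discouraged
  for transit-time PWV).
- Special-population rule sets (pregnancy, pediatrics) are out of scope.
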