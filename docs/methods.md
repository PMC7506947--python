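# Methods

## The estimation problem

A handball throw produces a sharp, isolated burst of wrist acceleration.
Its peak Euclidean norm `a` (in g) relates to the ball release speed `v`
(m/s) approximately log-linearly, and the relation shifts with sex and
throw type. The package implements the estimation method built on that
observation — measure `a` with a wrist-worn accelerometer, measure `v` with
motion capture in a validation session, fit

    v = β₀ + β_log · ln a + β_sex · 1[male] + β_type + ε,   ε ~ N(0, σ_ε),

and use the fitted model to estimate speed from acceleration alone — plus
everything needed to validate it: a synthetic study generator, the kinematic
and accelerometer measurement chains, the four model specifications (Base,
Sex, Type, Full, nested subsets of the predictors), 10-fold cross-validation
and a three-level calibration assessment.

The log transform matters: peak accelerations are right-skewed (they grow
roughly exponentially in speed), and the published coefficients are only
dimensionally sensible under the natural log of acceleration expressed in g
(Base model at 100 g: −4.9 + 6.4·ln 100 ≈ 24.6 m/s; base-10 logs or m/s²
units give nonsense speeds). Both the base and the units are nevertheless
configurable in `accel.log_peak`.

## Synthetic study generator (`synthdata`)

The generator emulates the validation protocol: 19 participants (8 female,
11 male), five throws of each of five types per session in randomised
order, 475 throws in total, throws 3 s apart.

Speeds are built in two layers:

* **systematic speed** `v_sys = m_type + δ·1[male] + s_i + η`, with per-type
  cohort means `m_type` = (13.7, 15.8, 21.0, 22.6, 20.9) m/s for the low/
  medium/maximal standing, standing-with-run-up and jump throws, sex offset
  δ = 2.4 m/s, per-participant skill offset `s_i ~ N(0, 1.2)` (level of play
  from amateur to professional), and per-throw variation `η`;
* **observed speed** `v_obs = v_sys + ε`, with `ε ~ N(0, σ_ε)`, σ_ε = 1.63
  m/s, the residual around the acceleration relation.

The accelerometer peak is planted by inverting the relation on the
noise-free part: `ln a = (v_sys − β₀ − β_sex·1[male] − β_type)/β_log`, with
the published Full-model coefficients as defaults. Consequently
`v_obs = β₀ + β_log ln a + β_sex 1[male] + β_type + ε` holds *exactly* with
ε independent of all predictors. That placement of ε is deliberate: putting
the noise anywhere else (e.g. drawing the observed speed first and pushing ε
into the acceleration) correlates the regressor with the error and biases
OLS toward zero, which would contradict the identities the validation rests
on. With ε independent, the generator *induces* the headline numbers rather
than asserting them:

* cross-validated MAE of the correctly specified (Full) model
  → `E|ε| = σ_ε√(2/π) = 1.30 m/s`;
* hold-out R² → `1 − σ_ε²/Var(v_obs)`; the configured within-type SD
  (2.7 m/s) plus the spread of the type means gives overall speed SD
  ≈ 4.36 m/s, hence R² ≈ 1 − 1.63²/4.36² ≈ 0.86;
* pooled out-of-fold calibration slope → 1.00 and mean calibration → 0.

`within_type_speed_sd` (2.7 m/s) is the *marginal* within-type SD of
observed speed; the generator decomposes it internally into the sex-mixture
variance `δ²p(1−p)`, the skill variance, σ_ε², and assigns the remainder
(≈1.34 m/s SD) to η. Configurations that leave no room for η are rejected.

Speed clipping to the per-type cohort ranges defaults to lower-bound-only
clipping of `v_sys` (`clip_speeds="low"`). This affects <1% of throws,
happens *before* the acceleration inversion (so the log-linear relation
stays exact; it merely truncates the regressor distribution, which OLS
tolerates), and bounds the smallest plantable peak at
`exp((9.4 − 9.0 − 2.4 + 5.0)/2.7) = 3.04 g` — which is what makes automated
segmentation provably recover every throw. Two-sided clipping of both
`v_sys` and `v_obs` (`clip_speeds="full"`) keeps all truth speeds inside the
cohort ranges but censors the outcome and therefore deflates MAE and
attenuates coefficients; it exists for range-containment checks, not for
the default study.

**Signals.** Each throw's marker pair is a straight-line trajectory whose
speed ramps up over 0.25 s with a raised-sine profile peaking — with zero
slope — exactly at the release frame, then stays constant (ballistic
flight). The zero-slope peak keeps the 20 Hz zero-phase filter's effect on
the release-frame speed under 2%. The hand tracks the ball at a 5 mm
lateral offset until one frame before release and then stops within one
frame, so the ball–hand distance increase first exceeds the 1 cm criterion
exactly at the planted frame (for protocol-range speeds; rare noise-tail
throws below ~7 m/s detect one frame late, with the correct speed either
way). The accelerometer stream carries one raised-cosine pulse per throw
(0.15 s wide, on a random unit direction, peak norm equal to the planted
peak) over Gaussian background noise (0.03 g per axis, norm ≪ any throw
peak).

**What the generator does not emulate**: real arm kinematics (no joint
sequencing — only the observables the pipeline consumes), marker dropout
and relabelling, accelerometer timestamp jitter (the 500 Hz grid is exactly
uniform), wristband movement artefacts, and sensor saturation. On the last
point: the published Full-model relation itself assigns peaks above 200 g
to fast throws about 2σ out (`exp((28 − 12.3)/2.7) ≈ 334 g`), so the
generator does not clip at the nominal ±200 g range — hard saturation would
corrupt the planted peaks and with them the regression identities. The
range is carried as stream metadata only. Passing tests therefore show that
the *statistical pipeline* is correct under its stated model, not that the
method survives real-world artefacts; external validity needs a real
cohort.

## Kinematic measurement chain (`kinematics`)

Filtering uses scipy's digital Butterworth (order 2 per pass) run forward
and backward (`filtfilt`, odd-reflection padding). The cutoff is the −3 dB
point of a single pass, so the two-pass amplitude gain at 20 Hz is exactly
0.5. Away from the cutoff the digital (bilinear-transform) response differs
from the analog formula `1/(1+(f/fc)⁴)` by frequency warping — at 60 Hz
(= fs/4) the two-pass gain is `1/(1 + 3.732⁴) ≈ 0.0051`, not 1/82; the
tests assert the warped value since the digital filter is the instrument
actually used in practice.

Conventions that the release criterion leaves open are fixed and
configurable: frames are 0-based; the "increase per frame" compares
consecutive frames k−1, k; the speed is read at frame k (`speed_frame=
"release"`; `"before"` reads k−1). The criterion is applied to *filtered*
positions (the stated processing order filters positions first). The
forward difference leaves the final frame speedless, so a release at the
final frame raises the no-release error, as does a trajectory with no
qualifying frame; the pipeline surfaces these with the throw id rather than
discarding silently. On generated data the chain is unbiased to within
−0.01 m/s (measured over 100 throws) with a worst-case error ≈ 0.02 m/s,
dominated by the filter's smoothing of the speed peak.

## Accelerometer chain (`accel`)

The norm needs no resampling or filtering (the peak of a norm is
grid-independent for isolated smooth pulses, and the protocol describes no
accelerometer filtering), so peaks are computed on the raw stream.
Segmentation takes local maxima of the norm above `min_peak` with maxima
closer than `refractory` merged into the larger (scipy `find_peaks` with a
distance constraint), then windows ±`refractory`/2 around each peak.
Defaults: `min_peak` = 2.5 g — below the generator's 3.04 g floor, an order
of magnitude above the background norm — and `refractory` = 1 s, far below
the 3 s protocol spacing. A 10 g threshold, sometimes a tempting round
number, would provably drop the weakest low-intensity throws (the published
relation puts them at 3–7 g). This segmenter emulates manual peak-picking
on clearly separated throws; segmenting free-play streams with unknown
throw counts is an explicitly different (and unsolved-here) problem.

## Models (`models`) and validation (`validation`)

Fitting is OLS (statsmodels) on an explicit design matrix with fixed column
order and treatment coding (references: female, jump throw), with 95% CIs
from the t distribution on residual degrees of freedom — the conventional
choice where the CI construction is not otherwise specified. Rank-deficient
designs (e.g. single-sex data under the Sex spec) raise an error naming the
collinear column. Throws are treated as independent observations, mirroring
the original analysis; the ~25 throws per participant are in fact clustered
(shared skill offset), which inflates apparent precision of participant-
level contrasts — noted, not fixed (no random effects).

Cross-validation assigns rows to k = 10 folds by a seeded uniform random
permutation (fold sizes differ by at most one; not stratified or grouped by
participant — the simplest faithful reading, with the clustering caveat
above). R² (`1 − SSE/SST`, SST about the hold-out fold's own mean) and MAE
are computed within each hold-out fold and reported as across-fold mean and
SD; calibration metrics use the pooled out-of-fold predictions, a single
number each: mean calibration = mean(predicted) − mean(observed),
calibration slope = OLS slope of observed *on* predicted (slope < 1 means
predictions are too spread out). Moderate calibration is a local-averaging
curve over 20 equal-count bins of predicted values, drawn with the
calibration and identity lines in one panel per model. Reported rounding:
slope to 2 decimals, mean calibration to 4.

## Problem sizes and reproducibility

All randomness descends from one root seed per study (structure,
per-throw and per-session signal seeds derived via `SeedSequence`), so
every artifact is bit-reproducible from its manifest. A full default study
(475 throws, both signal chains, four fits, four cross-validations) takes
about one second; the default test suite runs in well under a minute.
`scripts/acceptance.py` averages the stochastic summaries over 20 replicate
studies — the single-study Monte-Carlo spread of, e.g., the fitted sex
coefficient (SE ≈ 0.15) is comparable to the widths being checked, and
averaging reduces that spread without moving any estimand.

## Known limitations

* Synthetic validation only: the generator reproduces the assumed model, so
  these results demonstrate correctness of the pipeline, not field validity
  of the method (which requires an independent cohort).
* Sidearm throws and other untested throw variations are out of scope, as
  is counting or classifying throws in continuous free-play recordings.
* The published Type/Base/Sex-model coefficient values and the cohort SD
  columns describe the original laboratory sample; the generator uses them
  as defaults but the analysis does not (and cannot) re-derive them from
  first principles.
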