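# Methods

## Frame convention and units

All computation happens in a fixed lab frame: X mediolateral (positive
toward the subject's right), Y anterior-posterior (positive = walking
direction), Z vertical up. The instrumented leg is canonically the *left*
leg, so medial = +X; right-side recordings are mirrored (X coordinates and
X force components negated) before anything else. Positions are stored in
mm and forces in N; positions are converted to metres only inside the KAM
computation. Body-weight normalization uses g = 9.81 m/s².

## Signal conditioning and stance segmentation

Force-plate channels (GRF and COP — both originate from the plate) are
filtered with a fourth-order Butterworth low-pass at 15 Hz applied forward
and backward (zero phase lag). Marker channels are used as recorded; the
downstream spline fit provides their smoothing. Stance phases are
rising/falling crossings of a 20 N vertical-GRF threshold with a 5-frame
debounce (short dropouts bridged, short blips discarded); phases touching
the edges of a recording or outside 0.2–2.0 s are dropped. A step is kept
only if the vertical force on the non-assigned plate stays below 20 N for
the whole stance (clean single-plate landing). Each stance is resampled by
linear interpolation to 101 points, 0–100% inclusive, so "first half of
stance" is exactly samples 0–50. Missing marker samples are linearly
interpolated when the gap is ≤ 10 frames; otherwise the enclosing step is
dropped. Filtered vertical GRF is clipped at zero after resampling (the
zero-phase filter can undershoot slightly near heel strike).

## Kinematic quantities

* Pelvis center: centroid of the LASI/RASI/LPSI/RPSI markers.
* Knee joint center (KJC): midpoint of the lateral and medial femoral
  epicondyle markers; if the medial marker is absent, the lateral marker
  offset medially by a configurable half knee width (default 50 mm).
  How study protocols estimate KJC varies; the midpoint convention is
  exposed in config.
* Foot progression angle (FPA): signed angle of the horizontal
  calcaneus → 2nd-metatarsal-head vector from +Y,
  `fpa = degrees(atan2(−v_x, v_y))`, toe-out positive. The per-step FPA is
  evaluated on markers averaged over 15–40% of stance (foot-flat window);
  the within-stance sampling instant is otherwise arbitrary.
* Relative toe-in angle: θ = mean baseline FPA − step FPA, so toeing in is
  positive.
* Static frontal-plane alignment: signed angle between the
  malleolus → epicondyle and epicondyle → hip-center vectors projected on
  the (X, Z) plane, valgus (knock-knee) positive.

## Lever-arm KAM

The external frontal-plane knee moment is the quasi-static moment of the
GRF about the KJC: with r = COP − KJC in metres,
`KAM = r_x F_z − r_z F_x` (N·m), the anterior-posterior component of
r × F sign-flipped so adduction is positive on the canonical left leg.
Both the vertical-force term and the mediolateral-shear term are included
by default; `include_shear_term=False` reproduces vertical-only
implementations. Traces are normalized to %BW*HT. The first/second peaks
are the maxima over 0–50% and 50–100% of stance; the impulse is the
trapezoidal time integral over the stance duration.

## Pattern learning

Per toe-in step, the four pelvis-relative channels (KJC ML/AP, FCP ML/AP)
are differenced against the subject's pointwise-mean baseline cycle. Steps
are pooled across subjects with equal weight and grouped into 1° bins:
bin k covers [k−0.5, k+0.5) for k = 1..10; steps outside [0.5, 10.5) are
excluded. Bin means are smoothed by a least-squares B-spline of order 12
(degree 11) on an open uniform knot vector with no interior knots — the
minimal basis of that order, which spans polynomials of degree ≤ 11, so
fit error is non-increasing in the order. Both the order and the interior
knot count are configurable. A bin empty across the whole cohort is
synthesized by linear interpolation over the bin label between the nearest
populated bins (linear extrapolation from the two nearest at the edges)
and flagged in provenance; under the linear-response model this fill is
exact up to spline residue.

LOOCV learns a library from all-but-one subject, synthesizes the left-out
subject at the integer bin nearest their mean θ from their own baseline
mean cycle, and compares against their measured toe-in gait: per-channel
trajectory RMSE (mm), KAM-trace RMSE and first-peak MAE (%BW*HT), each
aggregated as mean ± SD over subjects. The reference first peak is the
mean of the per-cycle peaks; because the maximum of a noisy trace is
upward-biased, the first-peak MAE sits above the trace RMSE at realistic
noise even when the learned patterns are exact.

## Synthesis

Offsets are applied to the subject's mean baseline cycle (not per step):
pelvis-relative channels get the curve values added, and the lab-frame
KJC/COP mediolateral channels used for the KAM are shifted by the same ML
offsets — the pelvis is treated as stationary relative to the lab over the
cycle average, so pelvis-relative and lab-frame ML shifts coincide. The
KJC vertical coordinate and all GRF channels are copied from baseline
bit-identically. Extrapolation outside the library's bins is refused.

## Predictor

OLS with intercept on six features standardized to zero mean and unit
variance (population SD) using training data only. Splits are assigned at
the subject level: subjects are shuffled with the seed; round(0.1 N) each
(minimum 1) go to validation and test. Standard errors come from the
residual variance and the normal-equations inverse; p-values are two-sided
t with n − p − 1 degrees of freedom, uncorrected. A singular or
zero-variance design raises a collinearity error naming the offending
features. Feature subsetting supports ablations such as the toe-in-only
model. Evaluation reports MAE ± SD, both R² variants (coefficient of
determination of the predictions and squared correlation of the
actual-vs-predicted best-fit line), and the mean signed error
(actual − predicted, so underprediction is positive) aggregated per
subject across angles with a t-based 95% CI. The validation split is
reserved for order/feature sweeps.

## Simulator

The generator emulates what the pipeline consumes, not musculoskeletal
dynamics. Per subject, clinical features are drawn from configurable
normal distributions (height 171.6 ± 8.9 cm, weight 70.2 ± 12.4 kg, speed
1.25 ± 0.12 m/s, valgus 0 ± 3°, baseline FPA 3.97 ± 4.91°, clipped to
plausible ranges). Within a stance (duration 0.65 ± 0.02 s):

* vertical GRF = body weight × (two Gaussian bumps at 25%/75% plus a broad
  mid-stance term), solved linearly so the curve passes through 1.10/1.05
  BW peaks and a 0.75 BW trough, tapered by √sin(πs) to zero at the
  edges; ML and AP shear are small sinusoids (3% and 15% of BW);
* the KJC sits ~5.5% of height lateral of the midline; the COP lies
  medial of the KJC by a lever arm of 25 + 14·sin(πs) mm minus
  1.5 mm per degree of valgus, which yields a cohort-mean baseline first
  peak of ≈ 3.1 %BW*HT — the magnitude reported for adult cohorts — and a
  realistic two-peaked KAM;
* the toe-in response adds θ·g_c(t): by default the KJC moves medially at
  +1.2 mm/° and the FCP laterally at −2.0 mm/° under an early-stance
  Gaussian envelope (peak at 25% stance), with smaller AP responses under
  a mid-stance envelope. θ is drawn per step as N(target, 1.0°) truncated
  to [0.5°, 10.5°); subject targets cycle the integers 1–10 so all bins
  are covered. White marker noise of 1.5 mm SD (configurable) is added per
  step.

Raw-trial generation places markers and force series on their own time
bases (100 Hz / 1000 Hz), including swing-phase interpolation, optional
crossover contamination of the other plate (5% of steps), and records the
20 N threshold-crossing frames of its own unfiltered force signal as the
event ground truth. A separate direct feature-response generator produces
regression rows with exactly known raw-scale slopes (standardized-scale
β with toe-in dominant, divided by the analytic feature SDs) for
coefficient-recovery and CI-coverage oracles.

What the simulator does not model — soft-tissue artifact, step-to-step
correlated variability, asymmetric gait, GRF changes with toe-in,
non-linear θ responses — bounds what passing tests show: they validate the
estimation machinery (filtering, segmentation, binning, spline averaging,
lever-arm mechanics, OLS inference) under the stated response model, not
the biological fidelity of any learned pattern.

## Numerical choices and limitations

* Problem sizes in the test suite and acceptance script follow the study
  structure: 12-subject paired cohorts (120 toe-in steps), 138-subject
  synthesis cohorts, 1380 entries, 200-replicate coverage runs.
* Spline evaluation clips stance percent to [0, 100]; no extrapolation.
* Bin assignment uses round-half-up at bin edges ([k−0.5, k+0.5)).
* The library stores per-bin step counts, interpolated bins and a config
  hash in provenance; artifacts are versioned JSON and loading verifies
  the version tag and per-(channel, bin) completeness.
* Only linear marker-gap filling is supported; C3D ingestion and toe-out
  patterns are out of scope.
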