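# Methods

This note documents the models, parameter choices and numerical conventions
behind `armuse`, and what the synthetic cohort does and does not emulate.

## Epoch construction

Ground-truth labels are defined on 30 fps video frames with a
movement-primitive taxonomy.  Primitives collapse to three classes:
functional (reach, reposition, transport, communication gestures),
non-functional (stabilize, idle), and whole-body movement (WBM: gait,
transfers, wrist movement secondary to other body parts).  Frame labels are
resampled to the 50 Hz sensor clock by a causal floor mapping — the sample at
time *t* takes the label of frame `floor(t·30)` — never interpolating
categorical data.  Each 1-s epoch then takes the **modal class** of its 50
samples.  How a mixed epoch should be labelled is genuinely open; our
conventions are:

* an epoch is WBM-excluded only when WBM is the strict modal class (tolerant
  of one-or-two-frame annotation jitter at segment boundaries);
* a functional/non-functional tie breaks toward functional, favouring
  sensitivity for sparse functional movement;
* a trailing partial window is dropped.

WBM epochs are removed from all classification denominators: secondary wrist
acceleration during locomotion would otherwise contaminate the
non-functional class.  Time alignment between the video and sensor clocks is
assumed resolved upstream; recordings must share t = 0.

## Activity counts

Per axis: linear resample 50 → 30 Hz, fixed-coefficient 21-tap IIR band-pass
(pass-band ≈ 0.29–1.63 Hz, gain 0.965) applied at 30 Hz, decimation to 10 Hz
(every 3rd sample), rectification, dead-band (< 0.068 g → 0), saturation at
2.13 g, quantization at 0.01664 g per count unit, and summation of the ten
per-second values of each epoch.  Axes combine by vector magnitude, so
per-axis counts are integers while magnitudes are non-negative reals
(consistent with non-integer published thresholds such as 20.1).

Numerical conventions: the 30 Hz series is padded with 5 s of its first value
before filtering and the pad discarded, so a constant (gravity-only) input is
evaluated at filter steady state — its DC response (gain ≈ 0.044) falls below
the dead-band and yields exactly zero counts.  Epoch windows are half-open
`[k, k+1)` s aligned to t = 0.  Because the filter is causal, a DC offset
leaves a residual that decays over the first seconds; epoch counts are exactly
shift-invariant once that transient has died (verified in tests).

## ROC-optimal thresholds

AUC is the Mann–Whitney probability with ties counted half, computed from
midranks; its 95% CI uses DeLong's placement-value variance (no installed
package provides DeLong, so it is implemented here and cross-checked against
`sklearn.metrics.roc_auc_score` for the point estimate).  The optimal cutoff
maximizes Youden's `sens + spec` over the candidate set of **observed count
values plus +∞**, classifying with `>=`; objective ties resolve to the
smallest cutoff.  This is deterministic and matched against exhaustive
brute-force enumeration in the tests.  Whether the original cutpoints arose
from observed-value candidates or midpoints between them is not documented;
observed values are standard cutpoint-search practice.  Group-level fits pool
all subjects' epochs without reweighting; per-subject imbalance is reported,
not corrected.  Subjects lacking one class are skipped (with a warning) in
per-subject fits.  Empirical caveat: the Youden maximizer is an argmax
(cube-root-rate) estimator, so single-cohort cutoffs at n ≈ 10⁴ epochs carry
~10% sampling noise even when sensitivity/specificity are tightly estimated.

The conventional comparison uses `> 2` counts (unilateral) and `> 0` (the
per-side component of the bilateral rule), exactly as printed in the
validation literature.  Bilateral activity — prediction and ground truth — is
the conjunction of the two sides; no third model is fitted, since separate
bilateral thresholds have been shown to perform equivalently.

## Logistic-regression classifier

Preprocessing: 3-sample median filter per channel; gravity = zero-phase
2nd-order Butterworth low-pass at 0.25 Hz of the acceleration; body
acceleration = residual.  Features per 50-sample epoch (47 total): mean, SD,
RMS and range of each body-acceleration and gyro axis and of their
magnitudes; inter-axis correlations of body acceleration (xy, xz, yz);
per-axis gravity means (posture proxy); dominant-frequency bin, power at the
dominant bin, total 1–10 Hz power and spectral entropy of the two magnitude
signals (unwindowed DFT of the 50-sample epoch, 1 Hz resolution — the
simplest deterministic choice at this window length); and the barometric
slope.  Degenerate-window conventions: zero-variance correlations and the
spectral entropy of an all-zero window are 0.  The exact feature list of the
original analysis was not published; this set is our stand-in spanning the
same spatial/frequency domains and sensor modalities.

Model selection: grid over penalty ∈ {ridge, lasso} × 7 log-spaced strengths
C ∈ [10⁻³, 10³] (the original grid is unpublished), each point evaluated by
leave-one-subject-out CV with **per-fold z-score standardization fitted on
training folds only** — the per-fold scaler statistics are stored in the CV
report so the no-leakage contract is directly auditable.  Folds whose
training data contain a single class are excluded with a warning.  The
winner is the first grid point attaining the best mean validation accuracy;
it is refit on all data.  Classification uses probability ≥ 0.5, inclusive.
No class weighting is applied: performance is reported under the natural
~1:4 functional:non-functional imbalance.

## Evaluation

Sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, accuracy
`(tp+tn)/total`, PPV `tp/(tp+fp)`, NPV `tn/(tn+fn)`, reported to two
decimals in percent.  Zero-denominator measures are emitted as missing
(NaN), never as 0 or 1, so low-prevalence subjects cannot silently distort
per-subject distributions.  Fugl-Meyer bands: mild 43–66, moderate 29–42,
severe 0–28 — the published bands leave 19–28 unassigned and we fold the gap
into "severe", consistent with the severe/moderate boundary at 28/29 in the
cutoff literature, making the bands exhaustive.  Spearman correlations
(threshold vs FMA) require ≥ 4 pairs and return missing for constant input.
Count descriptives use linearly interpolated quartiles.

## Synthetic cohort

The generator defines the study conditions for every test:

* **Subject profiles.** Functional prevalence per side is a normal draw
  clipped to [0.01, 0.95]: affected mean 0.25, SD 0.194; unaffected mean
  0.46, SD 0.119.  The WBM fraction is N(0.50, 0.15) clipped to [0, 0.9]
  (roughly half of recorded epochs are whole-body movement).  Fugl-Meyer
  scores are uniform over the observed 16–65 range.  One global seed feeds
  per-subject seeded streams (subject id hashed into the seed sequence), so
  any subject is reproducible independently of cohort size.
* **Class-conditional counts** are zero-inflated log-normals per (side,
  class).  Functional and WBM cells are calibrated from the published
  quartiles: the zero atom occupies the lowest `zero_mass` of probability,
  `log_scale` comes from the IQR of log counts, and the median anchors
  `log_location` exactly (the outer quartiles are then matched to within a
  few percent — a two-parameter fit cannot absorb quartile asymmetry).
  Functional `zero_mass` = 0.05, implying a conventional-threshold
  sensitivity of 0.95, which matches the published operating point.  The
  non-functional cells have median 0, so the quartile rule is degenerate;
  instead (zero_mass, log_location, log_scale) are solved from three
  published points of the class CDF: P(X ≤ 2) and P(X < optimal cutoff) from
  the reported specificities, and P(X ≤ Q3) = 0.75.  The resulting affected
  mixture reproduces AUC ≈ 0.88 and a Youden cutoff ≈ 19–20 without either
  being imposed.
* **Impairment coupling.** The affected-side functional log-location shifts
  linearly with the Fugl-Meyer deficit (0.6 log-units across the simulated
  range, centred at FMA 40.5), reflecting the lower acceleration magnitude
  of hemiparetic movement.  The shift is symmetric about the cohort centre,
  so pooled medians stay calibrated.
* **Raw mode** synthesises 50 Hz signals: a slowly wandering unit-gravity
  vector, 0.5–5 Hz band-limited bursts whose per-epoch amplitude is the
  class-conditional count draw scaled by 0.004 g per count, white sensor
  noise (5 mg accel, 0.2 dps gyro), a 1.8 Hz common-mode oscillation on both
  wrists during WBM epochs, and a random-walk barometric channel.  Raw-mode
  realism is necessarily heuristic — per-class count distributions are
  published but raw-signal spectra are not — so raw mode is used for
  pipeline-level properties (schema equality with counts mode, monotonicity
  of counts in burst amplitude, zero counts at zero amplitude), not for
  distributional calibration.

What passing tests show — and don't.  Calibration tests demonstrate that the
analysis recovers the parameters of the generating mixture and reproduces
the published descriptives *under the model's assumptions* (log-normal
intensities, epoch independence, exact labels).  Real recordings have
autocorrelated epochs, label jitter, and movement classes that are not
log-normal; performance numbers on synthetic cohorts characterize the
estimators, not clinical accuracy.

## Problem sizes

Defaults were chosen so every stage is statistically stable at desk scale:
the acceptance script uses 14 subjects × 1500 s in counts mode (~21k epochs
per side, giving group operating points stable to ~1 point) and 8 subjects ×
120 s in raw mode for the feature/LOSO stage; calibration checks use 10⁴–4·10⁴
epochs.  Mixture-optimum recovery averages the fitted cutoff over 10
simulation seeds because of the cube-root noise noted above.

## Known limitations

* The count-chain coefficients are the published 5-significant-figure IIR
  approximation; devices with different analog front-ends may need
  recalibrated dead-band/saturation constants.
* Only 1-s epochs are supported (the 2-s historical convention can be
  emulated by summing adjacent epochs).
* The feature set and hyperparameter grid are stand-ins for unpublished
  originals; coefficients should not be interpreted clinically.
* Per-subject ROC fits require both classes; severely impaired simulated
  subjects with prevalence near the 0.01 floor can be skipped at short
  durations.
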