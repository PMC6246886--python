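# Methods

This note documents the models, numerical choices and limitations of
`reachdecode`. It is the package's own account of its science; every
number quoted here is computed by the test suite or the acceptance
script, not asserted from elsewhere.

## The problem

During a 3D center-out reach, cortical field potentials recorded over
sensorimotor cortex carry a linear, lagged representation of movement
kinematics: band-power changes (mu/beta suppression, gamma increase)
and a slow time-domain deflection (the local motor potential, LMP)
co-vary with hand speed and velocity. The package implements the full
offline decoding analysis for such recordings — feature extraction,
hierarchical decoding, surrogate-based significance testing, cross-arm
transfer, and forward-model interpretation — and, because the clinical
recordings that motivated it are not publicly distributable, ships a
synthetic-data generator whose ground-truth encoding makes every stage
testable.

## Task and kinematics model

Each trial is: center hold (Hold-A, 1 s), planning delay (2 s), reach
(1 s), peripheral hold (Hold-B, 0.5 s). Targets are the eight corners
of a 0.5 m cube centered on the start position, balanced within a
session (corner counts differ by at most one) in seeded random order.
Trials are concatenated into a continuous session with a 1 s return
reach and a 0.5 s inter-trial hold — both free parameters: the task
protocol does not constrain them, but continuous voltage synthesis and
realistic baseline statistics need them.

Reaches follow the minimum-jerk profile `x(τ) = x0 + D(10τ³ − 15τ⁴ +
6τ⁵)`, whose bell-shaped speed peaks at `(15/8)·D/T`. The 10 %-of-peak
speed threshold used for movement onset and movement/rest labels
crosses this profile at τ ≈ 0.0865, so ≈ 83 % of the reach duration is
labeled movement; the tests derive both numbers from the profile at
run time rather than hard-coding them.

Tracker noise is modeled as Gaussian positional jitter (SD 2 mm)
low-pass filtered at 2 Hz. White jitter would be wrong here: at 100 Hz
sampling it differentiates into ~0.3 m/s speed noise, an order of
magnitude above the onset threshold; real motion-capture error is
dominated by slow drift and tremor-band wobble.

Axis convention: +x anterior→posterior toward the subject, +y toward
the subject's left, +z downward.

## Voltage synthesis (forward model)

Each channel sums, at 1200 Hz:

* seven band-limited carriers — Gaussian noise band-passed to the
  canonical bands (theta 4–8, mu 8–12, beta1 12–24, beta2 24–34,
  gamma1 34–55, gamma2 65–95, gamma3 130–175 Hz) — each multiplied by
  `baseline · exp(w_s·s(t − lag) + w_v·v(t − lag))`, so log band power
  is linear in the lagged kinematics;
* a slow DC-coupled component linear in lagged speed and velocity,
  which the Savitzky–Golay LMP recovers;
* `1/f²` background noise (unit RMS, spectrally shaped in the Fourier
  domain with the lowest bins floored);
* an optional mains sinusoid (default 60 Hz, off unless requested).

Carriers are noise rather than sinusoids deliberately: an
autoregressive spectral estimator should see realistic smooth spectra,
not line spectra. Encoding lags live on the 50 ms frame grid in
[−1000, 500] ms, negative meaning neural activity leads kinematics.

The default ("strong") encoding gives every channel gamma2/gamma3
increases with speed, mu/beta1 suppression, and velocity tuning along
directions that cycle through the cube diagonals so all three
components are identifiable. The slow-potential speed weights
alternate in sign across channels; with a common sign the
common-average reference would subtract the (deterministic, shared)
component from every channel. These defaults were fixed at design time
as the package's stated world; with them, a single speed-tuned gamma2
channel shows window-level log-power/speed correlation above 0.7,
which is what "strong" means here.

For cross-arm negative controls, the "orthogonal" second encoding is
band-disjoint rather than channel-disjoint: it lives entirely in
gamma1 (34–55 Hz) with no slow component. Channel-disjoint encodings
are not actually orthogonal at the feature level, because the
common-average reference mixes channels and re-injects the encoded
signal everywhere; band disjointness (with spectral insulation from
every band the default encoding uses) survives both referencing and
carrier roll-off. The generator does **not** emulate:
epileptiform transients, electrode drift, channel-count asymmetries,
movement artifacts, or cross-channel correlated noise. A green
end-to-end test therefore establishes that the pipeline recovers a
linear lagged encoding under realistic 1/f noise — not that it would
survive every artifact of a clinical recording.

## Signal conditioning

Common-average referencing per electrode group, then a zero-phase
(forward–backward) 4th-order Butterworth band-pass 0.1–260 Hz, then
2 Hz-wide second-order IIR notches at every mains harmonic below
260 Hz. The filter family, order and zero-phase choice are ours (the
analysis being reimplemented names none); zero phase matters because
features and kinematics must stay time-aligned for lag estimation.
Channel and trial exclusion are manual index lists, mirroring visual
review; there is no automatic artifact detector.

## Features

Spectral power is estimated per 300 ms window (50 ms steps) with a
Burg maximum-entropy AR model of order 75, evaluated in 2 Hz bins
centered 3–253 Hz. The Burg lattice recursion is implemented in the
package (numba-compiled, batched over windows) because no maintained
implementation exists in the supported dependency set; it is tested
against FFT-periodogram peak locations and spectral-flatness oracles.

Bin powers are log-transformed and z-scored against pooled baseline
windows (those whose centers lie between 200 ms after Hold-A onset and
Hold-A end, pooled over all trials of the session — per-trial
baselines would make the SD estimates noisy at 15 windows/trial), band
averaged, then z-scored a second time. The double z-score is the
point: it corrects the 1/f fall-off so each 2 Hz bin contributes
equally, and it makes baseline variance exactly 1 per band no matter
how many bins the band contains (verified by simulation in the tests).

The LMP is the value at the window center of a least-squares quadratic
(second-order Savitzky–Golay) fit to each 300 ms window, z-scored the
same way. "Window center" is `start + win/2` everywhere in the
package; the quadratic is evaluated exactly there, so the LMP
reproduces polynomial inputs of degree ≤ 2 to machine precision.

Kinematics are differentiated by central differences and averaged onto
the same window grid using a trapezoidal interval average, which makes
a linear signal window exactly to its center value (the last window,
which lacks its closing sample, falls back to the plain mean).

## Decoder

* **Lagged design.** Channels × 8 features × 31 lags (−1000…+500 ms in
  50 ms steps); frames without full lag coverage at session edges are
  dropped, never zero-filled.
* **Movement/rest classifier.** Elastic-net logistic regression on the
  8 features per channel, each at the lag maximizing |Pearson r| with
  speed (ties: smallest |lag|, then the leading sign). The (C,
  l1_ratio) grid is scored by sevenfold CV and refit on all training
  frames. Labels: speed > 10 % of the trial-specific maximum.
* **Two PLS regressions** (movement frames / rest frames) map the full
  lagged design to speed, Vx, Vy, Vz through one shared latent space.
  PLS is SIMPLS: its components are nested, so one fit per CV fold
  scores every component count 1..k_max (default 12) at once — this is
  what makes sevenfold component selection affordable at ~4000-column
  designs; equivalence with NIPALS (scikit-learn) on single-output
  problems is enforced in the tests.
* **Switching and renormalization.** The classifier (probability
  threshold 0.5) selects which PLS output each frame uses; the raw
  velocity vector is scaled to unit norm and multiplied by the
  predicted speed, so ‖v‖ = speed exactly. Negative predicted speed
  clamps to zero; an exactly-zero raw vector stays zero.
* **Trajectories.** Predicted velocities integrate (cumulative sum ×
  50 ms) into trajectories; a trial scores a "target hit" when the
  predicted endpoint displacement falls in the same octant (sign
  pattern on all three axes) as the actual displacement, integrated
  identically from the actual velocities so discretization cancels.
  Chance is 1/8.

Compute guards for desk-scale runs, all seeded and disablable:
classifier hyperparameter search subsamples to 3000 frames (final fit
uses all), and the rest-model PLS subsamples rest frames to 5000.
Analysis frames span each trial's full Hold-A→Hold-B window.

## Evaluation and surrogates

100 (desk preset: 20) random 7/8-of-trials training sets; accuracy is
Pearson r between predicted and actual speed/Vx/Vy/Vz over
concatenated held-out frames, plus percent targets hit. Two nulls:

* **Temporal surrogate** — training-trial kinematics are reassigned by
  a random trial permutation and circularly shifted on the frame grid
  (value multisets and autocorrelation preserved; alignment to the
  untouched neural features destroyed), and the two PLS models are
  retrained on them.
* **Feature-shuffle surrogate** — the trained PLS weight rows are
  permuted across (channel, feature) blocks, each block's 31 lag rows
  moving together; 100 (desk: 25) permutations per fold.

In both, the actual classifier gates movement/rest and the actual
model's predicted speed modulates the surrogate velocity direction, so
actual-vs-surrogate differences isolate kinematic prediction from
state classification. (The surrogate's own classifier would never be
consulted, so it is not retrained.) Surrogate speed correlations stay
well above zero by construction; surrogate velocity correlations
center on zero.

Group comparisons use a two-sided Wilcoxon rank-sum test: exhaustively
enumerated when both groups have ≤ 10 observations, otherwise the
normal approximation with tie and continuity corrections. The
Bonferroni family is computed from the analysis plan — parameters ×
hands × true/cross × surrogate methods, between-hand and true-vs-cross
comparisons, and the per-subject repetition — which for the reference
plan (5, 2, 2, 2, 4 subjects) gives m = 215 and a critical p of
0.05/215 ≈ 0.00023.

Cross-arm prediction applies a decoder unchanged (training lags and
weights intact) to the other arm's data; identical channel layouts are
required, and no channel matching is attempted.

## Interpretation

Decoder weights are converted to activation patterns by the forward-
model identity `A = Σ_X W Σ_ŝ⁻¹`, computed as `Cov(X, ŝ)·pinv(Cov(ŝ))`
with `ŝ = X_c W` (algebraically identical, avoids the p×p covariance;
pseudo-inverse relative cutoff 1e-10). For the classifier, `Σ_ŝ` is the
scalar variance of the decision score. Importance keeps the top 25 %
of |A| (stable index order on ties), reports per-channel and
per-feature shares of the selected mass (min–max rescaled per repeat,
then averaged across repeats — the rescale-then-average order is a
choice; the raw shares are also returned), and the peak-|A| lag per
retained channel × feature.

Movement-aligned statistics: one-sample t per electrode × feature ×
window against zero (the baseline), two-sample t between hands, all
corrected together by Benjamini–Yekutieli step-up FDR — BY, not BH,
because overlapping 300 ms windows correlate neighboring tests, and BY
is valid under dependence. Percent-active time courses are compared
between hands by lagged Pearson correlation (±500 ms, 50 ms steps;
positive lag = first curve leads).

Topography: values are projected onto a 2-D grid as a Gaussian-kernel
weighted average normalized by the local kernel mass, making every
grid value a convex combination of electrode values. Anatomical
localization is out of scope; coordinates are abstract 2-D positions.

## Reproducibility

Every stochastic stage draws from `numpy.random.default_rng` seeded
through `SeedSequence` chains from one top-level seed; identical
configuration and seed give bit-identical outputs, and the pipeline
manifest records a configuration hash plus SHA-256 checksums of every
output file.

## Known limitations

* The synthetic world is linear-in-log-power by construction; the
  pipeline's accuracy there is an upper bound, not a forecast for
  clinical data.
* SIMPLS and NIPALS differ slightly for multivariate targets beyond
  the first component; the package standardizes on SIMPLS.
* The temporal surrogate preserves per-trial value multisets exactly
  only for equal-length trials (wrapping truncates/repeats otherwise).
* EDF I/O is not provided (no EDF library in the supported stack);
  voltages serialize to `.npy` + JSON, kinematics and trials to TSV.
* The rest-model subsampling cap and the classifier CV cap trade a
  little statistical efficiency for a ~3× speedup; disable both
  (`rest_max_frames=None`, `clf_cv_max_frames=None`) for full-fidelity
  runs.
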