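# Methods

## Problem setting

A gesture-recognition model for a myoelectric prosthesis is trained on
surface-EMG frames and must keep working across *sessions* — independent
electrode applications, hours or days apart. Between sessions the signal
distribution drifts (electrode shift, contact-impedance changes,
physiological state), and a classifier trained on earlier sessions loses
accuracy on later ones. The package quantifies two remedies on a common
footing: adding a few *calibration* trials from the test session to the
training set, and enlarging the training set along its two axes (number
of sessions vs trials per session).

## Synthetic database model

Each trial is `active_s` seconds of gesture burst followed by `rest_s`
seconds of rest (defaults 3 s + 3 s at 1000 Hz, 8 channels; a 14-channel
2 kHz configuration is available via `GeneratorConfig.db6like()`).

**Texture.** Surface EMG is, to second order, amplitude-modulated colored
noise. Rest is Gaussian noise band-limited to 20–450 Hz at
`rest_noise_rms` (default 1, arbitrary units). The burst adds colored
noise shaped per channel by a second-order resonator and band-limited to
20–450 Hz, amplitude-modulated by a raised-cosine on/off envelope
(`ramp_s` = 100 ms ramps). The burst is scaled so the aggregate
active/rest RMS ratio equals `10**(burst_snr_db/20)` (default 20 dB).

**Gestures.** Each gesture has a per-channel activation gain map built
from two circular Gaussian bumps with gesture-dependent centres and
widths. Maps overlap between gestures and are deliberately *not* shifted
copies of one another (otherwise an electrode shift could map one gesture
onto another exactly, making the task unidentifiable). Spectral centre
frequencies stay near the 80–150 Hz bulk of the myoelectric spectrum with
only ±12 Hz offsets between gestures: spatial pattern, not spectrum,
carries most of the gesture information, as in real forearm recordings.

**Within-session variability.** Contraction force varies between trials:
a per-trial lognormal amplitude factor (log-sd `trial_gain_cv` = 0.1) and
per-channel jitter (log-sd `channel_gain_cv` = 0.05). Trials within a
session are therefore strongly redundant — which is what makes the
trials axis of the training-amount analysis saturate.

**Session drift.** One drift descriptor per session, shared by all its
trials: per-channel multiplicative gains `LogNormal(0, 0.6·drift_scale)`
(contact impedance), and a per-channel fractional circular shift
`Normal(0, 0.8·drift_scale)` in electrode-pitch units, realised as convex
mixing of the two neighbouring input channels (electrodes are re-applied
individually, so each channel shifts by its own amount). At
`drift_scale = 0` the descriptor is exactly the identity and, because
trial noise streams are keyed by (gesture, trial) only, all sessions
contain identical signals. The default `drift_scale = 0.5` puts the
cross-session task in the regime the protocol is designed for: baseline
accuracy well below ceiling, same-session calibration nearly closing the
gap. No quantitative characterisation of real inter-session drift was
available to calibrate against; the scale is a free parameter chosen once.

**What the generator does not emulate.** Motor-unit physiology, force
levels and fatigue trends within a session, non-stationarity inside a
burst, power-line interference, inter-subject variability. Passing the
directional experiments on this generator shows the pipeline measures the
drift/calibration mechanics correctly; it does not certify accuracy
magnitudes on real recordings.

## Preprocessing

The whole trial is filtered once with a 4th-order Butterworth band-pass
(20–450 Hz) applied forward–backward (zero phase), then framed on a
0-based grid: 128 ms windows, 64 ms hop, trailing remainder dropped.
Per-frame zero-phase filtering of 128-sample windows would be numerically
fragile, so filtering precedes framing. The Hann taper (symmetric, zero
endpoints) is applied only where a spectrum is computed — tapering before
amplitude statistics (RMS, MAV, WL) would bias them.

## Activity detection

Per frame, three log sub-band energies (80–150, 150–300, 300–450 Hz):
zero-phase band-pass per channel, per-channel mean square, summed over
channels, `log(· + 1e-12)`. Pooling channels gives a 3-D feature that
keeps the mixture well conditioned. A 2-component full-covariance GMM is
fitted by EM per session (each session has its own electrode application
and energy scale; pooling across sessions is available via
`per_session=False`): k-means++ initialisation from the seed, covariance
regularisation `1e-6·trace/d`, tolerance 1e-4 on the relative
log-likelihood improvement, at most 200 iterations, with the
per-iteration log-likelihood recorded (it is nondecreasing, and the tests
assert it). The *active* component is the one with the larger sum of its
mean log-energy vector — a rule invariant to component relabelling.
(A norm-based rule would misbehave: rest frames have strongly *negative*
log energies and hence large norms.) Frames with active-posterior ≥ 0.5
are labelled 1, then smoothed by a 5-frame centred majority vote with
boundary clipping; exact ties in clipped windows keep the original label.

## Features

Per channel and frame, in frozen column order: 3 sub-band RMS energies,
RMS, WL, MAV, ZC, SSC, AR(4) coefficients a1–a4 with the order-4
prediction-error variance, mean amplitude spectrum (mean one-sided FFT
magnitude of the Hann-tapered frame, all bins including DC and Nyquist);
then all C(C−1)/2 Pearson correlations in pair order x=1..C−1, y=x+1..C.
ZC and SSC use a pure sign rule (deadband ε = 0, configurable): inputs
are band-passed, so the baseline wander a deadband guards against is
absent. AR(4) is Yule–Walker on the biased autocorrelation, implemented
as a batched Toeplitz solve over all frames and channels at once; a
zero-variance channel yields correlation 0 with a warning. Zero active
frames yield an empty matrix with the full column schema.

## Protocol

Presets: `study` (7 sessions × 20 trials: train 1–2, validate 3,
calibrate/test 4–7, first 5 trials calibrate, final 15 test) and
`db6like` (10 sessions × 12 trials: train 1–3, validate 4,
calibrate/test 5–10, final 7 test). "First/final" trials are counted per
gesture in acquisition order. The four variants share one test set per
session; memberships are explicit (session, gesture, trial) triples and
train/test disjointness is asserted on construction. Training grids take
the first N sessions and first T trials per gesture; the study grid
(6 × 20) enumerates 120 training sets, the DB6-like grid (9 × 12) 108.

## Classification and scoring

Features are z-scored with training-set statistics only (std floored at
1e-12). The default classifier is an RBF soft-margin SVM with C = 1 and
kernel width from the median pairwise distance of the standardized
training rows (computed order-insensitively on a canonicalised
subsample), seeded and frozen across all variants of an experiment
(asserted by hashing the spec). Comparators (KNN, LDA, MLP, and gradient
boosting where installed) are available through the same contract for the
classifier-comparison table. Raw frame predictions are smoothed per trial
by a causal 3-frame mode vote (ties to the most recent raw prediction);
accuracy is the percentage of correctly classified frames after
smoothing. Per (variant, n_calib), accuracy is the unweighted mean over
test sessions; the improvement row is the cumulative-variant mean minus
the single baseline value.

The average-accuracy (AA) marginals average the grid over the other
coordinate; `fit_log_curve` fits y = a·ln(x) + b by OLS with
R² = 1 − SSres/SStot (R² ≡ 1 for constant y). Accuracy should rise
roughly logarithmically in the amount of data, and the session-axis slope
exceeding the trial-axis slope formalises "new sessions teach more than
extra repetitions".

## Experiment scales

The packaged experiments (`semgcal.experiments`) choose sizes that keep a
replicate at seconds-to-a-minute on one core:

* activity-detection recovery: 10 databases of 2 sessions × 3 gestures ×
  6 trials at 15 dB burst SNR, scored frame-by-frame against ground truth
  (a frame is truly active when ≥ 50 % of its window overlaps the active
  interval);
* drift study: 10 databases of the full study layout (7 × 3 × 20,
  `drift_scale` 0.5); active frames thinned to 12 evenly spaced per trial
  (they are strongly redundant within a trial, while the several hundred
  SVM fits dominate cost); the grid samples the trial axis on the ladder
  {1, 2, 3, 5, 8, 12, 20} — the AA value at a given trial count does not
  depend on which other counts are sampled, so this only thins the
  fitted curve's abscissa.

## Numerical choices and edge cases

* Silent frames: sub-band log energies are floored (`log(x + 1e-12)`);
  zero-energy AR fits return zero coefficients and residual.
* Constant features: standard deviation floored at 1e-12, warning logged.
* Degenerate density samples (all equal): a narrow Gaussian spike is
  returned with a warning.
* Kurtosis is Fisher (excess) by default, configurable to Pearson;
  moments use biased (population) estimators; cross-group spreads of
  skewness/kurtosis use sample (ddof = 1) standard deviation.
* PCA standardizes features first (heterogeneous scales); rank-deficient
  inputs return fewer components with a warning.
* Seeds: the pipeline derives per-stage seeds from the global seed;
  replicate seeds come from `SeedSequence([seed, i])`, kept below 2³¹.

## Known limitations

* Classifier hyperparameters are sensible defaults, not tuned values; the
  comparison suite reproduces the structure of a classifier bake-off, not
  any particular published numbers.
* Absolute accuracies on the synthetic generator are not comparable to
  accuracies on real amputee recordings; only directional and structural
  conclusions transfer.
* The generator's drift model is a surrogate (gains + fractional shift);
  it does not model rotation of deep vs superficial sources or
  session-level spectral changes.
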