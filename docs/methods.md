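# Methods

This note documents the models, numerical choices and limitations behind
`emg_swn`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem

Myoelectric interfaces decode intended motion from surface EMG (sEMG).
Classifier features built on raw sEMG amplitude are fragile for two
well-documented reasons: amplitude differs several-fold between people
(electrode placement, tissue, skin impedance), and it drifts within a
person across sessions (electrode reapplication, fatigue, impedance
changes). Classical remedies — z-score or min–max normalization against a
measured reference such as an MVC recording — require a calibration step
and inherit the drift of the reference itself.

## Sliding-window normalization (SWN)

SWN z-scores each channel against its own trailing window of `L_norm`
samples. With `m_t` and `s_t` the mean and population standard deviation
of channel samples `x_n` for `t − L_norm < n ≤ t`:

    y_n = (x_n − m_t) / s_t

Applied per step this re-normalizes a whole window; the *streaming*
contract used by the pipeline emits only the newest element `y_t` per
step, producing a single causal normalized stream that any downstream
feature window can consume regardless of its own length. The per-window
form is retained (`swn_window`) as the verification primitive, and the
streaming path is tested to agree with per-step batch recomputation
exactly.

Two properties carry the method:

* **Causality** — `y_t` depends only on samples in `(t − L_norm, t]`, so
  the transform runs in real time with no calibration recording.
* **Per-channel scale invariance** — `(a·x − a·m)/(a·s) = (x − m)/s`, so
  any stable multiplicative gain (the dominant between-subject and
  between-session difference) cancels identically. This is the mechanism
  behind transferring a classifier to a new user with no calibration.

Choices: the standard deviation uses denominator `N` (population form,
the numpy default); statistics are per channel; a zero-variance window
emits zeros with a warning rather than halting the stream (configurable).
During the first `L_norm − 1` samples of a trial no full window exists;
the stream is defined there by an expanding causal window (the first
sample, which has no spread, follows the zero-variance policy). These
warm-up samples are discarded downstream by the trimming rule below, so
the full-window contract is unaffected; defining them keeps every feature
window over the retained region well-posed even when `L_norm` and
`L_feature` are both at the grid maximum.

### Baselines

* **z-score** — per subject and channel, `(x − μ_train)/σ_train` with
  statistics from that subject's *training split only*; both splits are
  transformed with them. For a held-out test subject this is exactly the
  calibration measurement SWN avoids.
* **none** — identity.

## Signal chain

EMG is simulated/acquired at 2000 Hz and conditioned causally
(forward-only `sosfilt`, preserving real-time feasibility):
3rd-order Butterworth low-pass at the decimated Nyquist (the normalized
digital cutoff is clamped to 0.999 to keep the design well-posed),
keep-every-4th decimation to 500 Hz, then a 3rd-order Butterworth
high-pass at 30 Hz. Positions (500 Hz) are smoothed with a *zero-phase*
2nd-order 20 Hz Butterworth — phase matters for labels, not causality,
since labels exist only at training time.

### Features

Per channel, over a trailing window of `L_feature` samples at 500 Hz:
MAV (mean |x|), MWL (mean |first difference|), DRMS (RMS of the first
difference; both difference features use denominator `L_feature − 1`,
the number of differences), an STFT band feature (64-sample Hann window,
50% overlap — the hop is a package choice, configurable — magnitude
spectrogram averaged over time, then averaged over bins whose center
frequency falls in the closed bands 1–70, 60–100 and 100–250 Hz; the
low/mid overlap is intentional), and an SWT feature (stationary wavelet
transform, db2, mean |cD3| ≈ the 31–62.5 Hz band at 500 Hz; windows are
symmetrically end-padded to a multiple of 2³ and coefficients cropped
back, since grid windows are mostly not multiples of 8). `ALL`
concatenates the five (7 columns × channel).

The magnitude (not power) spectrogram is used for the STFT feature; the
averaging convention is scale-ambiguous and magnitude is documented as
the package's choice.

Feature rows are computed only at timesteps ≥ the *longest grid window*
(500 ms), whatever `L_norm`/`L_feature` are in force — so every
configuration yields the same row count (a 4.6 s trial gives 82 rows) —
and subsampled by stride 25 to 20 Hz. Features are already
window-smoothed, so the decimation is plain subsampling.

### Labels

Marker positions → joint angles by the closed-form two-link planar
inverse kinematics; elbow angular velocity by forward difference × fs
(final sample replicated to preserve length, a choice that can affect at
most one trimmed-adjacent label per trial); targets coded flexion if
θ̇ ≥ +2 deg/s, extension if θ̇ ≤ −2 deg/s (thresholds inclusive), rest
otherwise. The angle convention — forearm rotated counter-clockwise from
the upper arm by the elbow angle, increasing elbow angle = flexion — is
fixed by requiring the forward/inverse kinematics round trip to be the
identity (enforced at 1e-6 degrees over the workspace). Labels and
features from one trial share the same 500 Hz sample indices before the
common stride-25 subsampling, so they align row-for-row.

## Synthetic cohorts

No public recordings exist for this task, so the package ships a seeded
simulator whose defaults are the study conditions every test runs under:
10 subjects, 12 channels (6 flexor-associated, 5 extensor-associated, 1
neutral wrist channel, matching the instrumented muscle groups), trials
of 2 s pre-rest + 2.5 s task + 0.1 s post-rest, 12 point-to-point elbow
movements among 4 target angles (40/70/100/130°), sessions of 36 trials
(12 movements × 3, shuffled), movement durations uniform on [0.8, 1.8] s
with a minimum-jerk profile, EMG at 2000 Hz and markers at 500 Hz
rendered by the package's own forward kinematics.

EMG generative model, per channel:

* **Carriers** — a Gaussian baseline (instrument/postural noise) plus a
  *sparse-impulse* activity carrier (Gaussian amplitudes gated by a
  Bernoulli(0.1) mask), both band-limited to 20–450 Hz and unit-RMS.
  Discrete motor-unit firings make active sEMG heavy-tailed
  (leptokurtic) at low-to-moderate contraction, and the kurtosis
  contrast between baseline and activity is what lets the MAV of an
  SWN stream carry class information (and decouple from windowed SD)
  even though SWN removes amplitude scale.
* **Activation envelope** — neural drive = rectified elbow angular
  velocity (flexors respond to positive velocity, extensors to negative,
  scaled by a 100 deg/s reference) plus an antagonist braking term
  proportional to deceleration (the triphasic pattern of point-to-point
  movements; co-activation weight 0.5, 400 deg/s² reference), passed
  through asymmetric first-order activation dynamics (τ_act 40 ms,
  τ_deact 200 ms: fast recruitment, slow relaxation) and shifted 50 ms
  earlier (electromechanical lead). Peak activation is 4× the noise
  floor at the reference velocity.
* **Amplitude heterogeneity** — three multiplicative log-normal levels:
  stable per-subject per-channel gains (log-SD 0.4; the between-subject
  differences that motivate normalization), per-session drift within a
  subject (log-SD 0.5; electrode reapplication/impedance), and per-trial
  jitter (log-SD 0.3; posture/fatigue fluctuation).
* **Structural subject differences** — each channel's coupling to the
  flexion and extension drives is subject-specific: the own-role
  response is scaled log-normally (log-SD 0.6) and every channel picks
  up half-normal cross-talk from the antagonist drive (scale 0.4; the
  neutral wrist channel sees cross-talk only). Electrode placement over
  muscle bellies and individual muscle-use patterns change *which*
  channels speak for a movement, not just how loudly — structure that no
  per-channel normalization can remove. Setting gains, drift, jitter and
  coupling spreads to zero yields exchangeable subjects.

These effect sizes were chosen to place the synthetic study in the
qualitative regime the method targets — un-normalized amplitude features
markedly less reliable than SWN features within a subject, and severely
degraded across subjects — and are frozen; the tests assert *directional*
results (orderings, signs) rather than any real-data accuracy value.

What the simulator does **not** model: spectral changes with contraction
level, motor-unit recruitment/firing-rate structure beyond sparseness,
crosstalk between channels, 3-D kinematics, marker noise (off by
default; a parameter exists), and force/torque. Passing tests therefore
show the pipeline's correctness and the method's mechanism under
realistic amplitude statistics — not performance on real recordings.

## Evaluation protocol

Per subject, consecutive blocks of 10 trials are randomly assigned 1:1
to train/test (seeded per subject). The classifier is unregularized
multinomial logistic regression with class-balanced sample weights and
an iteration cap of 6000 (scikit-learn; `C=inf` is the current spelling
of an unpenalized fit). **OWN** trains and tests within a subject;
**OTHER** trains on the pooled training splits of `k` other subjects
(all C(n−1, k) combinations, or a seeded subsample capped by
`combo_cap`) and tests on the held-out subject's test split. The
held-out subject never contributes training rows; z-score statistics
come from training splits only. Accuracy is percent correct; summaries
report the mean and two SDs (across per-subject means, and across all
subject × combination cells — which of the two a study should quote is
genuinely open, so both are provided). A best-over-window-grid selection
is available either per subject (default) or on the group mean.
Group comparisons use the two-sided Wilcoxon rank-sum test (asymptotic;
an exact option exists) with Bonferroni correction, significance 0.05.

The SD-vs-feature diagnostic computes, per subject and channel, the
Pearson correlation between the windowed SD of the *pre-normalization*
EMG and the MAV feature over the same retained windows, on the
unnormalized and on the SWN stream; zero-variance series yield missing
values excluded from the means.

A latency report (`benchmark-latency`) measures per-20 ms-tick wall time
of the streaming preprocessing chain with and without SWN; it is a
diagnostic, not part of the test suite's assertions.

## Problem sizes

The full design (10 subjects × 360 trials, a 5 × 5 window grid, and all
training-subject combinations) is far larger than needed to exercise
every code path, so the packaged study — used by the acceptance tests
and `scripts/acceptance.py` — runs 10 subjects × 180 trials (5 sessions
of 36), the 500 ms windows only, k = 9 (one combination per held-out
subject) and k = 1 (3 seeded combinations per subject). All sizes are
parameters; the full design runs unchanged, just longer.

## Known limitations

* Directional claims only: synthetic effect sizes are free parameters,
  so absolute accuracies depend on them; only orderings and signs are
  asserted.
* In the synthetic cohorts, OTHER models (nine training subjects, ~9×
  the training rows) score slightly *above* OWN models for every
  normalization method, whereas on real recordings within-subject
  models win clearly. The simulated subjects, even with structural
  coupling differences, remain more mutually consistent than real
  people, and the packaged OWN models train on 90 trials. The tests
  therefore compare normalization methods within a model type and never
  assert OWN versus OTHER.
* The simulator's class information after SWN lives in envelope
  dynamics and carrier kurtosis; real sEMG adds spectral cues SWN
  preserves, so SWN's synthetic accuracy is, if anything, conservative
  in mechanism coverage.
* With `L_norm = L_feature` at the grid maximum, feature windows near
  the trial start include expanding-window warm-up samples (see above);
  rows at later timesteps are unaffected.
* The synthetic SWN stream's MAV retains a small residual *positive*
  correlation (~+0.1) with the windowed pre-normalization SD: at
  movement onset the activation envelope rises faster than the trailing
  normalization window adapts, and the opposing effects (heavy-tailed
  activity carrier, slow deactivation) cancel this positive lobe only
  partially at the frozen physiological settings. Real surface EMG, with
  stronger non-Gaussianity and slower envelope dynamics than the
  generator models, should sit lower — near zero or below.
* The asymptotic rank-sum test is inaccurate for very small groups with
  complete separation; use `exact=True` there.
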