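# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of the `vigivoice` pipeline. Everything
stated here is computed by the package's tests or scripts; nothing is
imported from external data.

## Study design emulated by the generator

The synthetic corpus reproduces a 7-subject isolation study: subjects
enter an isolation chamber at 10:00 on day 1 and stay awake ~60 h.
Speech is recorded roughly every 6 h; psychophysiological test (PPT)
batteries run every 6 h offset by 3 h from the recordings. The default
composition is 74 recordings — per-subject in-isolation slot counts
(9, 9, 10, 10, 10, 10, 10) (two subjects miss the final recording),
five subjects add a baseline recording 24 h before the study at the
same time of day, and one subject records again 10 min after isolation
ends. Each subject completes 10 PPT batteries. Unique nearest-session
alignment then yields exactly 68 aligned samples: the 5 baselines have
no counterpart session and the post-isolation recording finds no free
session.

Recording times carry seeded uniform ±20 min jitter (baselines 0 to
+20 min so they stay inside the validity window) because real
"approximately 6 h" schedules are not exact; actual jitter magnitudes
are a config knob, not a claim. Recording durations are uniform in
105–495 s by default; the test suite uses 12–16 s clips (the modulation
analysis needs ≥ 10 s to resolve 0.1 Hz) to keep runs fast — reported
test-suite numbers therefore describe the short-clip corpus.

**Wake time** is identified with the isolation start (subjects presumed
awake from 10:00 day 1); baseline recordings are assigned latency 0.
Latent fatigue is F = latency / 3600 min clamped to [0, 1] (60 h full
scale).

## PPT score model

Each of the four scores follows
`y = β₀ + β_L·(hours awake) + β_P·phase + u_subject + ε`.
Latency enters in **hours** — the slope units are not self-evident from
the reference coefficient table, and hours give plausible effect sizes
over a 60 h study (e.g. planned RT drifts 0.403 ms per hour awake ≈
24 ms over the study). The generating slopes default to the reference
fixed-effect estimates:

| test       | β_L (per h awake) | β_P (per unit phase) |
|------------|-------------------|----------------------|
| simple RT  | 0.653 ms          | −3.10 ms             |
| planned RT | 0.403 ms          | 1.22 ms              |
| memory     | 0.0286 errors     | 0.785 errors         |
| cognition  | −0.0256 s         | 25.8 s               |

Intercepts (320 ms, 40 ms, 4 errors, 240 s) and variance components
(subject SDs 30/8/1.5/35, residual SDs 25/8/1.5/15) are not part of the
reference table; they are fixed once at values plausible for trained
adult subjects — between-subject spread comparable to or larger than
session-to-session noise, and residual noise small relative to the
full-study systematic drift, as repeated-measures designs with
practiced subjects typically show. Memory scores are rounded to
non-negative integers because they are error counts. With this design,
refitting the mixed model on 40 subjects × 10 sessions recovers β_L
(planned RT) and β_P (cognition) within 2 standard errors
(`scripts/acceptance.py`).

Mixed models are estimated by **maximum likelihood, not REML**, so that
likelihood-ratio comparisons of nested fixed-effect structures are
valid; the LRT p-value is the upper χ²(1) tail of 2·Δloglik, negative
statistics clamped to zero. A simulated null factor rejects at
p < 0.05 at close to the nominal 5% rate (seeded 500-replicate
simulation in the test suite).

## Speech synthesis

The synthesizer is a deliberately minimal source-filter model — an
impulse train at the voicing fundamental through four second-order
formant resonators (500/1500/2500/3500 Hz), alternating with silent
pauses — not naturalistic speech. Only the statistical link between
fatigue and acoustics matters for testing the pipeline. Fatigue F
drives four drifts in directions reported for sleep-deprived speech:
pause proportion 0.15 → 0.45, fundamental 120 Hz → 96 Hz, per-segment
formant jitter SD shrinking by 70%, and a growing one-pole spectral
tilt. With these defaults, hundreds of the 1093 features correlate
|r| > 0.5 with F across the default corpus, so learnability of the
synthetic corpus is comfortable rather than marginal. `VoiceDriftParams.null()`
zeroes all four gains for control experiments. What the generator does
**not** emulate: phonetic content, prosody, speaker idiosyncrasy beyond
random per-recording acoustics, channel/noise conditions, or any
nonmonotone fatigue dynamics — so passing tests demonstrate pipeline
correctness, not real-world effect sizes.

## Feature extraction

Framing: 50 ms Hamming windows with a 10 ms hop (the standard reading
of "overlapping by 10 ms"; the literal 40 ms-hop reading is available
via `--hop 0.04`), pre-emphasis a = 0.97. FFT length is the next power
of two ≥ the window; the **magnitude** spectrum feeds a triangular mel
filterbank (filters 200 mel wide, spaced 100 mel, spanning 0 mel to
mel(Nyquist), count derived from the sample rate). Filters are
normalized to unit area so a spectrally flat input produces a flat log
mel spectrum. Log floor 1e−10; orthonormal type-II cosine transform;
coefficients 1–19 kept (c0 tracks overall level, which the energy
stream already carries).

Autocorrelation coefficients: the biased normalized autocorrelation
(r[0] = 1) of each frame, linearly interpolated onto 64 delays
log-spaced from 0.5 ms to 25 ms (periodicities 40 Hz–2 kHz), cosine
transform, coefficients 1–19; zero-energy frames yield zero vectors.

Deltas are simple first differences, edge-padded by repetition.
Functionals: quantiles use linear interpolation; skewness and kurtosis
use population moments, kurtosis is excess (normal ⇒ 0); zero-variance
streams get 0 for both.

Modulation spectrum: 4th-order Butterworth band-pass 300–3500 Hz
applied forward-backward (zero phase), full-wave rectification,
4th-order zero-phase low-pass at 80 Hz, anti-aliased decimation to
200 Hz (`resample_poly`; naive subsampling folds residual
rectification ripple into the bands), Hann window on the mean-removed
envelope, magnitude-squared spectrum integrated over 40 contiguous
log-spaced bands covering 0.1–50 Hz, normalized by the total in-range
energy.

Layout: [MFCC, ΔMFCC, ΔΔMFCC, ACC, ΔACC, ΔΔACC, energy, Δenergy,
ΔΔenergy] = 117 streams × 9 statistics + 40 bands = 1093, asserted
structurally and at runtime.

## Alignment

Each recording is uniquely assigned the nearest same-subject PPT
session. The default walks recordings **chronologically**, giving each
its nearest still-free session: on the interleaved ±3 h schedule this
keeps every gap near 3 h (mean 3.0 h on the default corpus). A
globally ascending-gap greedy variant (`method="greedy_gap"`) is also
provided but cascades on jittered schedules — once a recording's
neighboring sessions are taken it grabs an arbitrarily distant one —
which contradicts the ~3 h mean-gap structure of the design; Hungarian
minimum-total-gap matching (`method="optimal"`) is available and agrees
with the chronological default on this schedule. Score interpolation
between sessions is deliberately not implemented: it would presuppose
the latency–score relationship under study.

## Normalization

Gaussianization maps each feature's per-subject sample to standard
normal quantiles of the (tie-averaged) ranks, with offset
(r − 0.5)/n to avoid infinite quantiles. It runs over **all** of a
subject's recordings (baselines included) before alignment, matching
the stage ordering of the analysis it reproduces. z-standardization of
PPT scores uses the per-subject sample mean and SD (n − 1 convention,
under which [400, 500, 600] → [−1, 0, 1]) computed from the full
sample **before** cross-validation — deliberate protocol replication,
with the leakage consequence discussed below. An enrollment-style
`SpeakerNormalizer` (fit on reference recordings, serialize to JSON,
apply to new audio) supports fold-safe or deployment use.

## Cross-validated prediction

100 repetitions of randomized sample-level 10-fold CV. Per repetition,
test-fold predictions are pooled and scored: Pearson R (defined as 0
for the constant null model), MAE in target units, and
RAE = 100·MAE/MAE_null with the null model trained on identical folds
(hence RAE ≡ 100%, SD 0 for the null model itself). Means and SDs are
reported over repetitions; pooled-prediction Pearson is the headline R.
Phase targets are encoded as minutes of day; predictions are wrapped
modulo 1440 and additionally scored with the circular error. MLR with
p = 1093 ≫ n uses the minimum-norm least-squares solution on centered
data; an optional within-fold top-k univariate-correlation selection
stage exists but is off by default. SVR uses a linear kernel,
ε = 0.001, tolerance 1e−3, C ∈ {1, 0.01}, with the target standardized
internally for optimizer stability and predictions mapped back.

### Known limitation: rank-completion leakage

Normalizing before CV creates a structural information channel that is
independent of the acoustics. After per-subject gaussianization, each
feature column sums to zero within each subject; z-standardized targets
share the same identity, and the shared study schedule makes the
per-subject latency/phase target sets nearly identical across subjects.
A test sample's feature vector therefore equals minus the sum of its
subject's training-fold vectors, and its target obeys the same linear
identity — so any model that fits the training rows closely (the
minimum-norm MLR interpolates; linear SVR comes close) predicts test
folds above chance even when the synthetic voice drift is switched off
entirely. Control experiments in the test suite isolate the channel:
iid random features with iid targets score RAE ≈ 100%, globally
permuting targets destroys the effect, while permuting targets within
subjects does not. Consequences: (i) zero-drift "null" corpora do
not produce RAE ≈ 100% under this protocol (the dedicated acceptance
test records this); (ii) reported CV metrics on any corpus — synthetic
or real — mix acoustic signal with protocol leakage. Fold-safe
normalization (enrollment on training folds only) closes the channel
at the cost of departing from the replicated protocol.

Fold assignment is at the sample level, not the subject level, again
replicating the protocol; with multiple samples per subject this adds
the usual within-subject dependence caveat to all reported metrics.

## Problem sizes used by the shipped runs

The test suite exercises the full default 74-recording composition with
12–16 s clips, CV at 100 repetitions for acceptance checks and 2–25
repetitions for smoke tests, mixed-model recovery at 40 × 10, and the
LRT calibration at 500 simulated datasets of 8 subjects × 8 sessions.
`scripts/acceptance.py` uses the 40 × 10 design. These sizes were
chosen so a complete run stays comfortable on a single CPU while
keeping every statistical check adequately powered.
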