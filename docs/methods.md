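# Methods

## Problem setting

Surface electromyography (sEMG) measures the electrical activity of
skeletal muscle from the skin. A wearable forearm array — here four
channels over the finger-controlling muscles, streaming rectified,
low-pass-filtered *envelope* amplitudes at 50 Hz in the 0–10 mV range —
carries enough information to classify discrete hand gestures. The
obstacle to a shared, one-size-fits-all classifier is inter-user
variability: muscle geometry, electrode placement, activation strength and
timing all differ between people. gesturekit implements the opposite
strategy: small per-user (personalized) convolutional models, a versioned
per-user model store, and the evaluation experiments that quantify how much
personalization buys as a cohort grows more heterogeneous.

## Synthetic cohort model

No human data ships with the package; the `synth` module generates
envelope recordings from a two-layer parametric model.

**Gesture templates.** A gesture is a set of per-channel activation
profiles: onset and duration (as fractions of the repetition), a peak
amplitude in mV, and a shape (trapezoid with 15% rise/fall ramps, or a
gaussian burst). Banks are sampled so that each gesture recruits a
distinct channel subset; temporal parameters stay in a narrow band
(onset 2–6%, duration 85–95% of a cued repetition, peaks 4–8 mV) because
fine hand gestures share similar contraction envelopes — identity lives
mainly in the spatial recruitment pattern. A repetition therefore holds the
gesture for most of the recording, so nearly every analysis window overlaps
the activation.

**User phenotypes.** Each user is a static transform plus noise, drawn
once per cohort:

| parameter | distribution (at variability level *v*) | models |
|---|---|---|
| per-channel gains | lognormal, log-sd 0.4·*v* | muscle strength, electrode impedance |
| timing offset | normal, sd 0.12·*v* s | habitual early/late onset |
| timing jitter sd | 0.08·tanh(*v*)·U(0.5,1.5) s | per-repetition motor variability |
| channel mixing | (1−ε)·I + ε·(0.75·P + 0.25·D), ε ≤ 0.6, E[ε] ∝ 0.45·*v* | electrode shift and crosstalk |
| noise sd | 0.25 mV · lognormal(log-sd 0.3·*v*) | sensor and physiological noise |
| drift amplitude | 0.2·*v*·U(0.5,1.5) mV | slow baseline wander |

P is a per-user channel permutation and D a diffuse row-stochastic matrix:
a shifted sleeve reads neighbouring muscles, which *re-labels* channels
rather than averaging them — the property that makes different users'
gesture signatures genuinely collide in a pooled training set. Shift
severity ε is itself heterogeneous (uniform factor 0–1.5), so some users
wear the sleeve well and some badly. Within-user jitter saturates
(`tanh`) because repetition consistency is a property of the person, not
of cohort diversity. On top of the static transform, every repetition gets
a common-mode *effort* factor (lognormal, log-sd 0.25, disabled in
zero-variability cohorts) scaling all channels jointly: spatial ratios are
preserved, absolute amplitude is not a reliable cue — as in real sEMG,
where contraction strength varies trial to trial.

Synthesis of one repetition: render the template → apply the effort factor
→ per-channel gains → timing offset + jitter → channel mixing → sinusoidal
drift (0.05–0.2 Hz, random phase) → additive Gaussian noise → clip at zero
(an envelope is a rectified magnitude). At *v* = 0 every user collapses to
the identity phenotype, which is the null condition of the personalization
experiments; with noise also zeroed, recordings are bitwise identical
across users. All randomness flows through `numpy.random.SeedSequence`
spawn keys per (user, gesture, repetition), so datasets are pure functions
of (bank, phenotypes, config, seed).

An optional raw mode emits a white-noise carrier amplitude-modulated by the
envelope at 1 kHz, scaled so the rectified mean matches the envelope
(E|aZ| = a·√(2/π)); it exists to exercise the software envelope detector
(rectify → first-order RC low-pass at 3.6 Hz, unit DC gain → decimate to
50 Hz), not to be spectrally realistic.

## Preprocessing

Recordings are standardized per channel, z = (x − μ)/σ, with μ and the
*population* σ computed on training data only and persisted in the model
artifact; deployment reuses exactly these values. Zero-variance channels
are flagged and mapped to zero through an ε-guard (1e−8 mV). Standardized
signals are cut into 32-sample windows with 50% overlap (stride 16;
0.64 s at 50 Hz); incomplete tails are dropped so the model input shape is
fixed, and windows never span recording boundaries. Windows with mixed
per-sample labels take the majority label, ties resolved by the center
sample. Standardizing before windowing is algebraically identical to
standardizing each window, because the map is linear and per-channel.

## Classifier

A deliberately small 1D CNN: two Conv1D→ReLU→maxpool blocks (32 then 64
filters, kernel 3, pool 2, valid convolution) followed by five dense
layers (256→128→64→32→*n*), ReLU between all but the last. The output
width is set per user from the gesture bank; all other shapes are
unchanged by the class count. The network, its backward pass, and Adam are
implemented directly in numpy (im2col convolution via
`sliding_window_view` + `einsum`), which keeps training single-threaded
and bitwise reproducible under a seed; the backward pass is verified
against finite differences in the test suite. A default 4-channel 3-class
artifact serializes to ≈1.1 MB.

Training: Adam at learning rate 0.001 on softmax cross-entropy,
mini-batches of 32 reshuffled each epoch from a seeded generator, a
stratified 20% validation split fixed across epochs, a minimum of 10
epochs, and early stopping once validation loss has not improved for
`patience` consecutive epochs (default 5; the experiments use 6–10 with
max 60–100 epochs). The artifact carries the weights of the
best-validation-loss epoch, so its stored metrics match its behaviour.
Prediction applies softmax and takes the argmax, ties to the lowest class
index; windows are evaluated one at a time so results do not depend on how
a stream was batched (BLAS reductions differ across batch shapes at the
last bit — this is what makes streaming ≡ batch an exact, not approximate,
contract).

## Registry and streaming

The per-user store is a plain directory tree (JSON metadata, zip model
artifacts, JSON-lines prediction logs), append-only: profile edits create
new revisions, and artifacts whose gesture map no longer matches the bank
are marked stale via marker files rather than deleted. `latest_artifact`
returns the newest non-stale version; an audit walks the store and checks
referential integrity (artifact → profile revision, log entry → artifact).
State lives entirely on disk, so independent processes agree.

Streaming inference keeps a ring buffer of the last 32 raw samples per
user, standardizes with the artifact's stored scaler, and emits one
classification per stride (16 samples = 320 ms at 50 Hz), stamped with the
window's last-sample timestamp. A timestamp jump greater than twice the
nominal sample period declares a stream gap and resets the buffer, so no
window mixes pre- and post-gap samples; a single lost packet (2× period
exactly) does not reset. Latency instrumentation is observational only —
wall-clock durations are hardware-dependent and carry no acceptance
threshold.

## Evaluation experiments

Both experiments compare two arms on byte-identical per-user window sets —
only model sharing differs. The personalized arm *is* the pooled arm run
on a single-user subset (one code path, model seed derived from the sorted
user tuple), so at cohort size 1 the arms coincide and the gap is exactly
zero by construction. Windows are split 80/20 per user (stratified by
gesture); each arm fits its own scaler on its own training windows.
Accuracy is window-level validation accuracy, macro-averaged over users;
repetition-level accuracy (majority vote over a recording's windows) is
available separately.

**Group-size scan.** 12 users all performing a shared 8-gesture bank
(6 × 2 s repetitions per gesture). For each subset size U ∈ {2, 4, 8, 12}:
one cross-user model on the pooled windows of the first U users versus U
personalized models, averaged over 5 seeds, with architecture and training
configuration (max 60 epochs, patience 6) held identical between arms. At
variability 2.5 the personalized−cross gap is positive at every U and
grows with U; at variability 0 (clones) pooled data is exchangeable with
per-user data and the gap vanishes.

**Live protocol.** 7 subjects, each assigned 3 random gestures from a
shared 10-gesture bank, 5 repetitions each (4 s repetitions, so each
subject contributes ~165 windows); personalized models (3 classes) versus
one cross-user model whose class space is the union of all assigned
gestures — the shared model faces its true deployment task, scoring every
window against every class. Training uses max 100 epochs, patience 10.

A `data_provider` hook on the scan accepts externally loaded per-user
splits in place of the synthetic cohort, so a real multi-user dataset can
be plugged into the same harness.

## Haptic codec

Messages are rendered on a 10-motor ERM sleeve as timed motor events.
A symbol's pattern is a set of non-overlapping events per motor; a message
concatenates symbol patterns separated by a 100 ms inter-symbol gap
(duration = Σ symbols + (len−1)·gap). Maps are injective by construction
and fully config-driven (JSON); the default letter map codes A–Z as
single-motor pulses with position and duration coding (10 motors × 150/
300/450 ms). The software decoder inverts encoding by maximal-munch event
matching and exists to verify codec integrity — the intended receiver is a
human wearer. Requesting more symbols than a style's (motor, duration,
intensity) grid holds raises a capacity error.

## Numerical and design choices

- Population (n) rather than sample (n−1) standard deviation in the
  scaler: deployment consistency over unbiasedness.
- Argmax ties and label-vote ties are broken deterministically (lowest
  class index / center sample).
- Early stopping never fires before epoch 10 even if patience is already
  exhausted; the stopping rule is exposed as a pure function
  (`simulate_early_stopping`) for direct testing.
- Artifacts are a versioned zip (JSON metadata + npz weights), not
  language-native pickles; schema mismatches raise, never misload.
- Out-of-order packets are dropped, not re-sorted, matching a lossy
  transport where throughput beats guaranteed delivery.
- Experiment problem sizes (12-user cohorts, 5 seeds, 60–100 epoch caps)
  are desk-scale choices: large enough for the qualitative contrasts to be
  stable across seeds, small enough to iterate on a laptop CPU.

## What the synthetic cohorts do and do not show

The generator reproduces the *structure* of inter-user sEMG variability —
static per-user amplitude, timing and channel-identity transforms plus
within-user trial noise — but not raw-signal spectral content, fatigue,
electrode lift-off, or nonstationary drift within a session. Passing
experiments therefore demonstrate that the pipeline's personalization
machinery behaves correctly under controlled heterogeneity (null case
clean, signal case favouring personalized models), not that any particular
accuracy number transfers to human subjects. The variability scale is
anchored qualitatively: level 0 = clones, level 1 = mild cohorts where a
pooled model remains competitive, level ≥ 2 = strongly heterogeneous
cohorts where personalization clearly wins.

## Known limitations

- The simulator's envelope amplitudes are calibrated only by the 0–10 mV
  physiological bound; no empirical amplitude distribution was available.
- Phenotypes are static within a cohort; life-stage drift is represented
  in the registry's versioning model, not in the signal generator.
- The CNN is trained in float64 on CPU; no GPU path, no quantization.
- The haptic decoder assumes patterns produced by its own encoder; it is
  a round-trip verifier, not a general acoustic/tactile segmenter.
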