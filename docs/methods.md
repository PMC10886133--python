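# Methods

## Problem and signals

The package classifies every overlapping analysis window of a
multimodal gait recording into one of six locomotion conditions —
level treadmill walking/running at 0.75, 1.25, 2.0 and 2.75 m/s,
walking on a 15 % incline at 1.25 m/s, and walking with a 10 kg load at
1.25 m/s.  Three modalities are fused: surface EMG from eight
right-leg muscles (gluteus maximus, rectus femoris, vastus lateralis,
vastus medialis, biceps femoris, tibialis anterior, gastrocnemius
medialis, soleus) and tri-axial accelerometers on the same sites, both
at 2000 Hz, plus vertical ground reaction force (GRF) at 1000 Hz.

## Synthetic data generator

Human recordings are not shipped; a generator produces trials with the
statistical structure the pipeline assumes.  What it emulates:

- **GRF**: each cycle is a double-hump stance profile (loading response
  and push-off, peak 700 N) held strictly above the 15 N event
  threshold for the whole stance, followed by a swing phase at 0 N, so
  every cycle contains exactly one upward 15 N crossing — the heel
  strike that defines cycle starts.  A 1 N Gaussian noise floor
  (clipped at 0 N) models force-plate noise; it is kept at the newton
  scale, far from the threshold, because treadmill force noise does not
  scale with EMG sensor SNR.
- **sEMG**: per muscle, a phase-locked activation envelope multiplies a
  Gaussian carrier bandlimited to 15–500 Hz (EMG is well described as
  amplitude-modulated broadband Gaussian noise).  Envelopes are wrapped
  Gaussians with muscle-specific peak phase and width (extensors in
  early stance, plantarflexors at push-off, tibialis anterior around
  swing, biceps femoris in terminal swing), a 0.15 baseline tone, and a
  0.35-weight secondary burst half a cycle away, reflecting the
  biphasic activity of lower-limb muscles and keeping every gait phase
  informative.
- **Class structure**: envelope amplitude grows affinely with speed
  (0.25 + 0.65·v), so amplitude is strictly increasing in speed across
  the four level classes at every phase.  The incline condition scales
  muscles non-uniformly (hip extensors and plantarflexors up to ×1.6)
  and delays bursts by 6 % of the cycle; the load condition scales the
  quadriceps group most (×1.5) with no timing shift.  The two factor
  vectors are deliberately non-parallel so that incline, load and plain
  speed changes move the 8-muscle activation vector in different
  directions; all six per-muscle mean envelopes are pairwise distinct.
- **ACC**: deterministic cadence-locked waveforms (harmonics 1–3 of the
  stride frequency with fixed per-sensor/axis mixing), with amplitude
  0.5 + 1.0·v.  The incline class shifts the harmonic phases; the load
  class differs from level-1.25 only by a ×1.03 amplitude factor, so
  acceleration features are strongly informative about speed and
  deliberately weakly informative about load, reproducing the known
  confusion structure of acceleration-only classification.
- **Noise**: per-channel additive Gaussian noise at a configurable SNR
  (default 30 dB) for EMG and ACC.  All randomness flows from one
  `SeedSequence`; per-channel streams are spawned from it, so output is
  bit-identical for a given (config, class, seed) and channels are
  statistically independent.

Default cycle durations are 1400/1150/870/660 ms for the four speeds
and 1180/1160 ms for incline/load — cadence rising with speed, with the
fastest class (1320 samples at 2000 Hz) inside the 1220–1600-sample
range of per-cycle lengths implied by the reference decision-count
table used for latency budgeting.

What the generator does **not** emulate: motion artifact and electrode
lift-off, inter-subject variability, electromechanical delay, stride-
to-stride cadence jitter, crosstalk between channels, or any
musculoskeletal dynamics.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the assumed signal
model, not field performance on human data.

## Preprocessing

Butterworth designs: 6th-order bandpass 15–500 Hz for EMG, 4th-order
lowpass 12 Hz for GRF, both applied forward–backward
(`sosfiltfilt`), which cancels phase exactly and squares the magnitude
response; the named order refers to the one-pass design.  Edge
handling uses odd-symmetric padding whose length is scaled to the
slowest pole of the filter (8 · rate / f_low samples, ≈ 1070 samples
for the EMG band edge at 15 Hz): a pad proportional only to the filter
order leaves edge transients that penetrate hundreds of samples at
these low normalized cutoffs.  With this pad the time-reversal
symmetry test (filter∘reverse = reverse∘filter) holds to 1e−9 in the
interior.  ACC mean subtraction is per trial, not per window.

## Windowing and arithmetic

Windows live on the 2000 Hz EMG timeline, are half-open
[start, start + W), 0-based, and never straddle cycle boundaries; a
cycle of L samples yields ⌊(L−W)/I⌋ + 1 windows.  This closed form
exactly reproduces the published per-cycle decision counts when cycle
lengths are reconstructed from the increment-10 counts via
L = (N−1)·10 + 140 (checked over all 42 participant × increment
cells).  The feature matrix is decimated by two (keep rows 0, 2, 4, …)
to match the GRF rate — decimation, not averaging, and applied to the
feature rows, not to the per-cycle decision-count arithmetic.  EMG
indices map to the GRF timeline by floor division by two.

Heel-strike detection uses a strict `>` threshold at 15 N with a
re-arm-below-threshold state machine (a flag disables the state
machine; on clean signals the two agree).

## Features and normalization

Standard time-domain myoelectric definitions: RMS = √mean(x²),
MAV = mean|x|, WL = Σ|Δx|, ZC counts sign changes with an optional
amplitude deadband ε (default 0), SSC counts interior samples whose
neighbouring slopes have product ≥ ε (default 0).  Each is verified
against an independent naive-loop oracle to 1e−12.  Min–max scaling to
[0, 1] is fit on training rows by default (leakage-safe); a
`normalization="all"` mode fits on the whole matrix before the split,
matching protocols that normalize first.  Constant columns map to 0
with a warning.  Column order is channels-major, components-minor, and
is fixed so saved matrices are portable.

## Classifiers and protocol

Per-trial split: final cycle tests, preceding four train.  Defaults
where the protocol leaves hyperparameters open: SVM uses an RBF kernel
with γ = "scale" and an inner 5-fold stratified cross-validated grid
over C ∈ {1, 10, 100}; KNN uses k = 5 (scikit-learn's distance
tie-breaking); QDA uses a 1e−4 covariance ridge — the smallest value
that reliably keeps class covariances full rank on min–max-scaled
matrices (larger ridges distort the strongly anisotropic per-class
covariances and cost accuracy); the decision tree is depth-unlimited
and seeded.  All four are delegated to scikit-learn; the package owns
the protocol, the confusion bookkeeping and the sweeps.  Accuracy is
reported in percent; classification error is 100 − accuracy.

Kruskal–Wallis rank ANOVA (via `scipy.stats.kruskal`) compares
accuracy distributions across settings, appropriate because the
feature and accuracy distributions are not normal; the degenerate
all-identical case returns H = 0, p = 1.

## Decision streams and latency

One decision per window, timestamped at the window's **end** index
(causality: a decision cannot precede its data).  The decision delay
is the cycle duration divided by the per-cycle decision count; the
latency budget is 15 ms to leave headroom for hardware and transfer
delays.  `delay_table` reconstructs each reference participant's cycle
length from the published increment-10 count, recounts windows at
increments 10–60, takes the across-subject minimum (the worst case a
deployed system must tolerate) and converts to milliseconds using an
explicit reference cycle duration.  That duration defaults to 641 ms,
the value consistent with the published delay row, but is an argument,
never hard-coded: it is a property of the gait being budgeted for, not
of the windowing arithmetic.  At 641 ms only increments 10 (5.88 ms)
and 20 (11.65 ms) stay in budget, which is why increment 20 — the more
accurate of the two — is the default.

Assistive ankle torque per class is a sum of Gaussian bumps over the
gait cycle scaled by 0.2 (assist, not replace).  Biological torque
curves are not tabulated anywhere in the package's inputs, so the
shipped per-class profiles are synthetic defaults (a push-off peak
near 48 % of the cycle whose amplitude grows with speed, incline and
load, plus a small early-stance bump) and fully configurable.

## Statistical design of the tests

- **Recovery**: at the default conditions the pipeline's mean held-out
  accuracy over ten seeds must be ≥ 95 % (measured ≈ 99.7 %).
  Per-window perfection is not attainable almost surely: the windowed
  RMS of a broadband carrier has an intrinsic coefficient of variation
  of ≈ 8 % (≈ 2·B·T degrees of freedom per window) that does not
  shrink with sensor SNR, so any finite class separation leaves a
  nonzero per-window error probability.  Per-cycle majority votes,
  which aggregate tens of decisions, are asserted to match the trial
  label exactly.
- **Chance floor**: with training labels permuted, raw accuracy is a
  biased chance statistic here for two reasons — windows are strongly
  correlated within a trial (the effective unit is the trial, not the
  window) and window counts are class-imbalanced (slower gait, longer
  cycles, more windows), which pulls a noise-fit classifier toward the
  majority class.  The tests therefore use **balanced** accuracy, whose
  expectation is exactly 1/6 under any label-independent predictor,
  averaged over permutation replicates, with the binomial interval
  evaluated at the per-class unit count.
- All stochastic tests are seeded; generator parameters above are the
  study conditions and are not varied per test.

## Known limitations

- QDA reaches ≈ 92 % rather than ≥ 95 %: window features within a
  class are multimodal across gait phases, which a single Gaussian per
  class cannot represent.  SVM and KNN are unaffected.
- The confusion that remains at high SNR is concentrated on
  load-vs-level at 1.25 m/s, by construction the closest class pair.
- Cycle durations are constant within a trial; stride-to-stride
  variability would blur the ACC phase code and lower accuracy.
- The torque profiles are qualitative placeholders for controller
  plumbing, not biomechanical references.
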