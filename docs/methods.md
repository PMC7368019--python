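# Methods

This note documents the models, parameter choices and numerical decisions
behind `veptools`: what the synthetic cohorts contain, how each analysis
stage is defined, and where the design was genuinely open.

## Signal model

### Steady-state (SSVEP) runs

A run is 100 s at 1,000 Hz.  The neural response to a 14-Hz square-wave
flicker is modelled directly as a harmonic sum,

    s(t) = Σ_k  A_k · g · sin(2π k f t + φ_k + Δφ),    k ∈ {1, 2},

rather than by convolving a flash train with an impulse response: only the
harmonic amplitudes and phases at 1f and 2f enter any downstream analysis,
so the harmonic sum *is* the sufficient description.  The 10-ms flash
train itself is still generated as the event list.  `g` collects the
gain terms (disease effect × animal gain × wavelength factor) and `Δφ`
the phase offsets.

Background activity is 1/f ("pink") noise plus white noise.  The pink
component is produced by spectral shaping (amplitude ∝ 1/f, random
phases) restricted to the 1–200 Hz acquisition band of the amplifier
chain that this paradigm assumes (high-pass 1 Hz, low-pass 200 Hz);
without the high-pass restriction the sub-1-Hz 1/f tail dominates the
spectrum and no realistic steady-state spectrum results.  Defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| `harmonic_amplitudes` | 10 (1f), 5 (2f) | µV | 2f weaker than 1f, as typical for square-wave drive |
| `noise_pink_scale` | 6 | µV (SD) | a 1/f band starting at 1 Hz holds ~half its variance in [1, 2) Hz; this scale keeps the 1–4 Hz background below the 1f response so the averaged spectrum peaks at 14 and 28 Hz |
| `noise_white_scale` | 35 | µV (SD) | sets the side-bin noise floor so the default SNR at 1f is ≈ 4.5 (design band 3–5) and ≈ 2.5 at 2f; bin retention ≈ 97–100% |
| `band_low_hz`, `band_high_hz` | 1, 200 | Hz | the acquisition filter band |
| `rat_effect_sd` | 0.2 | log-units | per-animal log-normal amplitude gain |

The per-animal gain is a *single* scalar shared across electrodes and
sessions (a global-gain idiosyncrasy: reference electrode, skull and
tissue conductivity).  This is deliberate: a shared gain cancels exactly
under the within-animal z-scoring used by the classifier, so arbitrary
splits of the animals are not classifiable — the regime a chance-level
shuffled control presupposes.  Per-electrode animal gains were tried and
rejected: they make every random 13/13 split of the animals almost
perfectly classifiable, which contradicts the observed behaviour of this
assay (shuffled controls at chance, real-group accuracies below 100%).

### Flash-VEP runs

400 flashes at 1 Hz.  Each epoch is a sum of six signed Gaussian
deflections (P1, N1, P2, N2, P3, P4) with latencies defined relative to
stimulus *offset* (onset + 10 ms flash):

| peak | latency (ms) | width σ (ms) | amplitude (mV) |
|---|---|---|---|
| P1 | 30 | 6 | +0.30 |
| N1 | 60 | 10 | −0.25 |
| P2 | 95 | 12 | +0.20 |
| N2 | 140 | 16 | −0.15 |
| P3 | 200 | 20 | +0.10 |
| P4 | 280 | 25 | +0.08 |

Latencies and widths are spaced so neighbouring deflections pull each
other's extrema by well under one sample.  The same pink+white noise is
added.  Latency shifts (the disease effect) translate every bump; on the
1-ms grid a 4-ms shift moves each noiseless extremum by exactly 4
samples.

### Disease effect and cohort design

Two groups of 13 animals; the treated group's effect is confined to the
left superior colliculus (ipsilateral to the simulated unilateral
injection): SSVEP amplitude factor 0.84, phase offset +0.3 rad, VEP
latency shift +4 ms.  Controls are identity by construction (validated).

The amplitude factor is the one genuinely calibrated constant.  The
classifier's accuracy responds to it as a steep sigmoid (0.86 → ~55%,
0.84 → ~85%, 0.82 → ~100% at the default noise level), because the
between-class separation is compared with the tiny spread of 90-bin
averages.  0.84 puts the all-electrode analysis in the 84–93% accuracy
regime this assay reports while keeping the per-electrode amplitude
difference far below univariate detectability — the point of the method
is that the multivariate classifier sees what electrode-wise statistics
do not.

### Seeding

All randomness flows through `numpy.random.SeedSequence`: a cohort seed
spawns per-animal sequences, which spawn per-recording sequences in a
fixed order; the bootstrap spawns one sequence per iteration.  No global
RNG state is used anywhere, and identical seeds reproduce every artifact
byte for byte.

## Spectral stage

1-s bins at 1 kHz give exactly 1-Hz resolution, so 14 and 28 Hz are exact
bin centres; non-integer stimulation frequencies are rejected rather than
interpolated.  No windowing or detrending is applied before the FFT
(per-bin mean removal is available behind a flag, default off).  The
single-sided normalisation maps a sinusoid of peak amplitude A to A at
its frequency.

Side-bin noise is the RMS of the amplitudes in the four 1-Hz bins on each
side of the harmonic; at 14 and 28 Hz these windows overlap neither each
other nor DC.  An arithmetic-mean variant is available
(`method="mean"`) for sensitivity analysis; the RMS form is the default
because the SNR is defined against the RMS of the local noise.
Exclusion is strict (< 1 excluded, = 1 retained).  SNR sentinels:
amplitude > 0 over zero noise → +inf (retained); 0/0 → NaN (excluded).
Amplitudes (not powers) are used throughout, consistent with retaining
"Fourier amplitudes" as features; the exclusion decision would be
unchanged under squared units with a squared threshold.

## Bootstrap classifier

Without-replacement resampling partitions each feature pool into 13 × 90
bins per iteration — with a full 1,170-sample pool every bin is used
exactly once (tested).  When SNR exclusions leave a pool short of the
exact-partition demand the library raises; the pipeline then switches to
with-replacement resampling and logs it, rather than silently changing
the resampling law.

Z-scoring is within-animal across features (the reading of normalising
"across each synthetic rat"); the per-feature-across-animals axis is a
flag.  Under the within-animal axis it makes no difference whether
z-scoring precedes or follows pooling the two classes.  Phase is never a
feature.  The SVM uses the canonical defaults of common implementations —
RBF kernel, cost 1, width 1/(n_features · feature variance) — with no
hyperparameter search.  Folds are stratified and re-randomised each
iteration.  Per-class pools are kept separate (with one pooled sampling
pool the class labels would be meaningless).

Significance is the fraction of iterations with accuracy strictly below
the 0.5 chance level; fewer than 5% below chance is significant, and an
observed zero is reported as "p < 1/n_iterations".

### The shuffled control and small-sample CV pessimism

Cross-validated accuracy on label-permuted data is *not* centred at 50%
at n = 26: the held-out animals anti-correlate with the training class
means, and the tight clusters formed by 90-bin averages amplify the bias
(we measure ≈ 42% when the labels of the assembled synthetic animals are
permuted).  Two shuffle units are therefore provided:

* `shuffle_unit="animal"` (default): the 26 real animals' group labels
  are permuted each iteration and the per-class pools rebuilt from the
  random 13/13 split before synthetic animals are assembled.  This is the
  variant that lands at the 50% chance level a shuffled control is meant
  to demonstrate (the residual within-iteration split signal offsets the
  CV pessimism).
* `shuffle_unit="synthetic_rat"`: permute the labels of the assembled
  synthetic animals.  Runs measurably below 50% for the reason above;
  kept for comparison.

Relatedly, duplicating every animal into both classes does not yield 50%
either: the held-out copy's identical twin stays in training with the
opposite label and the classifier anti-predicts.  These are properties of
cross-validation, not bugs; the test suite asserts the true behaviour.

## VEP stage

Epochs run from stimulus onset to the next onset and are averaged
pointwise; the time axis is re-referenced to stimulus offset and
amplitudes converted to mV.  Under periodic stimulation the averaged
epoch is cyclic, so the default baseline window — the 50 ms immediately
preceding onset — indexes the (flat) tail of the epoch.

Peak windows are configuration, not code.  Defaults (P1 0–40, N1 30–80,
P2 60–120, N2 100–180, P3 150–250, P4 220–350 ms post-offset) are
calibrated to the synthetic templates; real data needs its own windows,
since the extraction this detector replaces was manual and used none.
Windows start after time zero because the sample at zero can carry the
stimulus onset/offset electrical artefact; no artefact subtraction is
attempted.  A window whose extremum sits on its boundary, or a flat
window, yields an explicitly unreliable peak (null latency/amplitude in
the output table), never a silent value.  Ties break to the earliest
sample.  The detector takes an arbitrary named-window set, since which
peaks exist differs by structure (P4 is cortical, for instance).

Latency recovery at 400 trials is within the 1-ms sampling resolution
for the narrow early peaks and within a few samples for the broad,
low-amplitude late ones (jitter grows with width and inverse amplitude);
the left–right *shift* contrast, averaged over a 5-animal, 2-wavelength
cohort, recovers an injected 4-ms delay with mean absolute error below
1 ms (asserted in the test suite).

## Circular stage

Phases are pooled across wavelengths and reduced to one circular mean per
(animal, side) before the two-factor test, respecting animal-level
independence; raw-bin pooling is a flag.  Neither mode is claimed to be
what any particular prior analysis did — the aggregation level is
genuinely underdetermined.

The Harrison–Kanji decomposition partitions chord-based sums of squares
of cell resultants.  For pooled concentration κ̂ > 2 (cut-off exposed as
`kappa_threshold`), F statistics with the 1/(1 − 1/(5κ) − 1/(10κ²))
correction are used and the interaction is testable; the residual uses
n − pq degrees of freedom.  For diffuse data a chi-square form applies
and the interaction is reported as null.

The diffuse branch is a two-component Satterthwaite approximation rather
than the single-factor form found in older toolboxes: a group resultant
fluctuates both along the pooled mean direction (variance
(1 + A₂)/2 − A₁² per observation, A_k = I_k(κ)/I₀(κ)) and perpendicular
to it (variance (1 − A₂)/2), so the chord sum of squares is a mixture of
two chi-squares; matching its first two moments gives the scale and
effective degrees of freedom.  At κ → 0 this reduces to
2·SS ~ χ²_{2(p−1)}.  The single-component form (df = p − 1) rejects
~15% of uniform-phase samples at α = 0.05 — exactly P(χ²₂ > 3.84) —
while the Satterthwaite form holds the nominal level (asserted by a
500-simulation type-I test).

Calibration of the analytic p-value is excellent through the decision
range (uniform to within Monte-Carlo error for p ≤ 0.5, and the α = 0.05
tail is exact); far above p ≈ 0.6 the F approximation compresses large
p-values, a known property of the chord-SS null.  The permutation oracle
in the test suite (stratified label permutation, same statistic)
therefore asserts agreement within 0.05 where both p-values are in
[0.01, 0.6].

## Formats and pipeline

The long table (one sample per row, with an events sidecar) is the
lossless interchange format; EDF (16-bit) is the standard biosignal
container, written by a minimal classic-EDF writer and read back through
an independent reader (mne), which the round-trip test exploits.
Condition metadata and events travel in JSON/CSV sidecars.  Amplitudes
are µV internally; VEP peak amplitudes are reported in mV.

Every output table carries the seed and a hash of the scientific
configuration; re-running with the same seed reproduces result tables
byte for byte.  No multiple-testing correction is applied across weeks or
peaks — the tables are inputs for external statistics tooling, and the
run log states this.

## Problem sizes in the test suite

The default test run simulates full-size single-week cohorts (26 animals,
5 wavelengths) for the classifier checks, reduced bootstrap counts
(200 iterations, tolerance widened accordingly) for the chance-level
calibration, a 5-animal 2-wavelength cohort for latency-shift recovery,
500 simulations for circular type-I error, and miniature cohorts for the
end-to-end determinism checks.  `scripts/acceptance.py` runs the
shuffled-label control at the full 1,000 iterations.

## What the generator does and does not emulate

It emulates: the recording design (electrodes, sampling, band, session
structure), stationary harmonic responses with realistic SNR, 1/f + white
background, between-animal gain variance, a unilateral multivariate-scale
disease effect, and flash-VEP morphology with a lateralised latency
delay.

It does not emulate: non-stationarity within runs (drift, movement
artefacts beyond the trimmed onset/offset), wavelength-dependent
physiology (wavelength is a label with optional gain factors), animal-
specific response *patterns* (see above — deliberately), harmonics above
2f, volume conduction between electrodes, or any biophysics of retina,
colliculus or cortex.  Passing tests therefore show that the analysis
machinery is correct and calibrated under its own assumptions, not that
real recordings satisfy those assumptions.
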