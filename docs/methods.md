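# Methods

This note documents the models, conventions and design choices behind
`peepwatch`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Signal chain and feature definitions

Audio is mono, `[-1, 1]`-normalized, at a reference rate of 51.2 kHz (the
rate is a parameter carried through all features; resampling is available
but off by default). Recordings are cut into contiguous, non-overlapping
half-minute analysis windows; a trailing partial window is dropped rather
than padded, because the energy features are duration-sensitive.

**Spectrogram.** Frames of 512 samples with a periodic Hann window and
50 % overlap (hop 256), no centering or zero-padding, giving
`1 + (N - 512) // 256` frames. The power spectrum keeps bins `k = 1..K`
with `K = 256`; the DC bin is excluded so the centroid's bin-index form
starts at `k = 1`. The framing is implemented directly (rather than via a
padded/centered library STFT) because the frame convention *is* the
feature definition: a unit test checks the per-frame centroid against a
naive direct-DFT oracle to 1e-9 relative error.

**Spectral centroid.** Per frame, `Ce(i) = Σ k·|Xᵢ(k)|² / Σ |Xᵢ(k)|²` in
bin-index space, mapped to kHz via `k · fs / n_fft / 1000`. Zero-power
frames have an undefined centroid and are excluded from the signal-level
aggregate (a frame-power-weighted mean) instead of being scored as 0,
which would drag the aggregate toward DC. An all-zero spectrogram raises
an error rather than silently returning 0. Reporting in kHz is a
convention chosen so that typical chick-call energy (1–4 kHz) makes the
2.03 threshold of the rule tree interpretable; the raw bin-index form is
also exposed.

**Energy.** `E = Σ x[n]² / fs` over the analysis interval. The spatial
integral in the physical definition of emitted energy collapses to the
single microphone position: with one uncalibrated receiver, only relative
energy is measurable. The kcal/kg *energy unit* is therefore
`C · E / (n_chicks · w̄)` with an explicit calibration constant
`C = 0.27` mapping relative acoustic energy to the kcal scale. `C` is a
package convention (chosen once so the default isolation scenario lands on
the ~15 kcal/kg magnitude reported for isolated chicks); absolute kcal are
not derivable from uncalibrated audio and all comparisons within a study
are invariant to `C`.

**Envelope.** Magnitude of the analytic signal (Hilbert transform), with
a 5 ms moving-average smoothing by default. For the tonal call model the
smoothed envelope of a peak-normalized call sits near 0.74× its waveform
peak, because the ripple contributed by the harmonics is averaged out;
detector intensity thresholds are specified on this smoothed-envelope
scale.

## Call detection and typing

Events are maximal runs where the envelope exceeds
`onset_threshold × noise floor`, with the noise floor estimated as the RMS
of the lowest decile of envelope values (robust in call-dense recordings).
Each run boundary is then refined outward to a lower hysteresis threshold
(0.5× the onset threshold) so onsets track the start of the attack ramp
(within ~10 ms) rather than the detection crossing. Refined runs are
merged across gaps under 20 ms and dropped under 30 ms.

The default onset threshold is 3× the estimated floor. Note the estimator
targets the *envelope* floor, which for Gaussian noise sits near 1.2× the
noise σ (Rayleigh mean); 3× leaves >3 dB of margin both to the weakest
default call (short call, amplitude 0.28) and against false triggers.

Typing is a total, deterministic rule evaluated in order of increasing
energy: an event no longer than 0.10 s is a **short call**; an event at
least 0.25 s long with mean envelope at least 0.45 is an **alarm call**;
everything else is a **peep**. The alarm intensity criterion is the *mean*
envelope over the event, not the peak: in dense group recordings,
overlapping peeps from different birds periodically reach the coherent sum
of their amplitudes (beat maxima), so a peak criterion cannot separate
chance pileups from genuine alarm calls, whereas sustained intensity
separates them cleanly (measured ≥ 0.51 for alarm calls vs ≤ 0.37 for
pileups across 40+ seeded recordings). All thresholds live in
`DetectorConfig`; the defaults are tied to the synthetic call templates
since no numeric criteria are published.

**Ground truth for detector benchmarks** is the overlap-merged annotation:
two calls that overlap in time form a single acoustic event that no
envelope detector can split, so the observable event count is the union of
annotated intervals (`SynthAnnotation.merged_intervals`).

## Synthetic data generator

The generator reproduces the study conditions rather than any particular
waveform corpus:

- **Call model.** Sinusoid at the fundamental plus two harmonics at
  −12 dB and −20 dB, random phases, Tukey (Hann-ramped, 40 % total ramp)
  amplitude envelope, renormalized to hit the template peak exactly.
  Default templates: peep 3.0 kHz / 0.15 s / amplitude 0.35; short call
  3.6 kHz / 0.08 s / 0.28 (≈3× less energy than a peep); alarm call
  2.5 kHz / 0.35 s / 0.85 with fast (0.8 s) repetition. No absolute call
  frequencies or durations are published for the three types, so these are
  field-plausible conventions, overridable per template. Each bird carries
  a ±4 % individual offset of its fundamental.
- **Group scenarios.** Per-bird call rate falls with group size
  (75 calls/min in isolation down to 10 at 15 birds, log-interpolated
  between anchors), matching the observation that isolation elicits
  continuous alarm calling while large groups call sparsely. Isolated
  birds emit only alarm calls; grouped birds emit peeps with a 25 %
  short-call share (5 % at 7 birds, where short calls were rarely noted).
  Call trains use a per-template refractory interval plus exponential
  waiting times; per-bird substreams spawn from one global seed, so a
  scenario is bit-reproducible independently of bird count. Chamber noise
  is Gaussian with RMS 24 dB below the alarm-call peak; the mix is
  rescaled only if it would clip.
- **Feature tables.** Rows (weight, flock size, energy unit, centroid)
  are drawn from zero-truncated normals parameterized by the published
  per-group means and standard errors. The underlying location of each
  truncated normal is solved numerically so its *post-truncation* mean
  equals the published mean — without this, the isolation energy row
  (mean 14.87, SE 12.5) would be biased upward by ≈2.8 kcal/kg. No SE is
  published for the centroid column; 0.15 kHz is used. Labels follow
  group size: distress (1), intermediate (3, 5, 7, 10), normal (15).

**Intermediate-class resolution.** Training requires binary labels. With
per-row short-call counts, `reassign_intermediate` maps intermediate to
normal when at least `cutoff` short calls were identified (short calls are
the calm-group vocalization) and to distress otherwise. Without counts,
the deterministic resolution implied by the decision rules is used:
intermediate groups of more than 6 birds are normal, smaller ones
distress. The direction of the reassignment is an interpretation — only
the fact that it is driven by short-call counts is documented in the
source material.

## Classification and evaluation

The rule tree uses strict comparisons exactly as published (boundary
values fall to the else branch) and never consults bird weight. The
published rule text is internally inconsistent on the final centroid
branch (one passage assigns both branches to distress); this package
follows the resolution stated in the same source's discussion and
conclusions: centroid ≤ 2.03 → normal.

Retrainable classifiers are standard scikit-learn inductions — kNN (k = 5,
standardized features), CART decision tree (Gini), random forest
(100 trees) — on a stratified, seed-deterministic 80/20 train/test split.
The "80 % to develop, 20 % to train" phrasing in the source is read as the
conventional 80 % train / 20 % evaluate, the only reading under which
held-out metrics exist.

Metrics: accuracy `100·(TP+TN)/total`; Cohen's kappa from the confusion
marginals (0 returned in the degenerate all-one-cell case);
cross-entropy in two forms. The distribution-level form implements the
published equation exactly as printed, `H(P,Q) = −Σ Qᵢ log Pᵢ` with
weights from the *estimate* Q (the textbook target-weighted form is a
switch away); base-2 logs by default. The classifier-level score in
`EvalReport` is the per-instance log loss `−mean log₂ q(yᵢ)` on predicted
probabilities (clipped at 1e-15): this is the only reading under which the
H ≤ 0.2 acceptance bar is attainable, since the distribution-vs-
distribution cross-entropy of even a perfect balanced prediction equals
the class entropy (≈1 bit). The t-test is Welch's by default (pooled
Student switchable); min-max normalization rejects constant vectors.

## Problem sizes in tests and the acceptance script

Detector benchmarks use 20 seeded 30 s recordings (alternating isolation
and 3-bird groups, ~1150 annotated calls); energy-ordering checks use two
to three 1–2 minute recordings per flock size (8–12 half-minute windows
each, mirroring the 12-windows-per-group design of the original study and
its 72-instance total); classifier benchmarks use ten 72-instance tables.
These sizes give Monte-Carlo error comfortably below the asserted margins
while keeping the full suite around ten seconds.

## Known limitations

- The call waveform model is tonal and stationary per call; real chick
  calls are frequency-modulated and noisy, so absolute spectral features
  (not the contrasts) will differ on real audio.
- No room acoustics: no reverberation, propagation loss or overlapping
  noise sources beyond the Gaussian floor. Detector recovery near 100 %
  on the synthetic corpus is an upper bound, not a field expectation.
- The window-level spectral centroid is computed over *all* frames, so in
  sparse recordings it is pulled toward the broadband noise spectrum;
  restrict to detected events (or raise the noise floor parameter) when a
  call-timbre centroid is wanted.
- The kcal calibration constant is a convention; only within-study
  contrasts of the energy unit are physically meaningful.
- Synthetic feature tables are separable by construction (labels are a
  deterministic function of group size, and group size is an attribute),
  so near-perfect retrained-classifier scores on them validate the
  pipeline's plumbing, not real-world classification difficulty.
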