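# Methods

`megdecode` implements a complete phrase-decoding analysis over multichannel
neuromagnetic (MEG-like) signals: a synthetic experiment generator, the
epoching/filtering/rejection pipeline, wavelet feature construction, three
decoders, and the evaluation protocol. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic study
does and does not establish.

## The synthetic experiment

Real recordings of the delayed-reading phrase task are not publicly
distributed, so the generator (`megdecode.synth`) produces datasets with the
statistical structure the analysis assumes:

- **Trial layout.** Each trial spans −0.5 to +4 s around stimulus onset at
  1 kHz: pre-stimulus rest (0.5 s), perception (1 s), preparation/imagined
  speech (1 s), production (2 s). Stage intervals are half-open in seconds
  relative to onset.
- **Class signal.** Each of the five phrase classes owns a spatio-spectral
  signature: sinusoidal carriers at class-specific frequencies inside named
  oscillation bands, with sparse per-channel amplitude patterns and Hann
  on/offsets covering 10% of each active stage (`edge_ramp_frac`, settable
  to 0 when a pure-sinusoid closed form is wanted). The production onset is
  jittered by a truncated normal (mean 0.25 s, SD 0.1 s, clipped to
  [0, 0.5] s) emulating reaction-time variability.
- **Units and SNR.** Background noise is 1/f (exponent 1 by default),
  independent across channels, unit SD — so amplitudes are in noise-SD
  units. `make_random_signatures` normalizes each class's flat-envelope
  multichannel RMS to 1, making the per-stage gain `stage_snr[stage]`
  literally RMS(signal)/RMS(noise) in that stage.
- **Stage SNRs.** Defaults are pre 0.0, perception 0.5, preparation 0.8,
  production 1.2: silent rest and the production > preparation > perception
  ordering the task structure implies (overt articulation recruits motor and
  auditory cortex on top of the preparatory activity). `carryover_gain`
  (default 0) optionally leaks the production signature into the following
  trial's pre-stimulus window, the mechanism proposed for above-chance rest
  decoding in this paradigm.
- **Artifacts.** Optional blink-like events (single <4 Hz high-amplitude
  Hann transients, peak 10–20 noise SDs, frontal channel subset) and
  cardiac-like ~1 Hz pulse trains (peak 3), scheduled per-trial as a Poisson
  process.

What the generator does **not** model: sensor geometry and field spread
(channels are indices), cross-channel noise correlation, non-sinusoidal or
broadband induced activity, trial-to-trial amplitude variability beyond the
onset jitter, and acoustic/jaw-motion channels. Passing tests on this data
therefore demonstrate the correctness and calibration of the pipeline — not
that real MEG phrases are decodable at any particular accuracy.

## Preprocessing

Epoching cuts fixed windows (−0.5 to +4 s → 4500 samples at 1 kHz) around
events; events whose window leaves the recording are skipped and logged.
Low-pass filtering is a 4th-order Butterworth below 250 Hz applied
forward-backward (zero phase), chosen so filter latency cannot shift stage
boundaries; the effective magnitude response is the squared single-pass
response. Trial rejection emulates visual artifact screening by amplitude
thresholding: a trial is dropped if any channel's peak exceeds the threshold
(default 6 robust SDs, 1.4826×MAD, for data of unknown scale) or any
channel is flat. On synthetic data with known units an absolute threshold
(e.g. 9 noise SDs, between the strongest class signal and the weakest blink)
separates artifacts more cleanly, and the analysis drivers use that.
Channel exclusion removes named bad sensors, preserving order (the 204→196
gradiometer configuration).

## Wavelet bands and RMS features

A 7-level db4 DWT (symmetric padding, to limit edge artifacts on 4.5 s
epochs) splits each channel into details d1..d7 and approximation a7. d1
(250–500 Hz) and d2 (125–250 Hz) are discarded as noise; the remaining
reconstructions are the band signals — high-gamma (d3), gamma (d4), beta
(d5), alpha (d6), theta (d7), delta (a7) — and their sum is the denoised
composite. Two caveats are inherent to the dyadic construction: the printed
band edges (e.g. gamma 31–58 Hz) are labels, the realized dyadic bands are
e.g. 31.25–62.5 Hz, and the short db4 filters leak measurably across edges
(a denoised white-noise signal retains roughly 10% of its energy above
125 Hz — the filter bank is not brickwall).

The baseline feature is the RMS of each (channel, band) pair within one
analysis stage, concatenated channel-major — 6 × 196 = 1176 values in the
full sensor configuration. `screen_features` ranks candidate statistics
(RMS, mean, median, SD, quartiles, tertiles, energy, windowed energy) by the
fraction of dimensions separating the classes (one-way ANOVA at α = 0.001,
with Tukey HSD confirmation on the significant dimensions). The
cross-correlation-matrix candidate is omitted: its dimension grows
quadratically in channels.

## Scalograms, tiling, augmentation

Scalograms are squared magnitudes of a complex Morlet CWT (ω₀ = 6
equivalent; `cmor2.0-0.9549`) over 64 (default; 32 in the scaled runs)
log-spaced center frequencies spanning 0.5–125 Hz — at least 4 voices per
octave across the named bands. Input is the denoised (<125 Hz) signal,
decimated 4× in the pipeline since 250 Hz sampling is lossless for in-band
content. Rendering takes log10(energy + ε), min-max normalizes per image
(matching the per-image normalization conventions of image classifiers),
maps through viridis, and resizes bilinearly — the scalar field is resized
before colormapping so ridge geometry is independent of colormap curvature.

The whole-head (spatial-spectral-temporal) feature tiles one scalogram per
sensor row-major into a rows×cols composite (14×14 holds 196 sensors; the
scaled runs use 5×5 for 25 channels). The sensor→cell order is ascending
channel id by default — the spatial arrangement is a recorded, overridable
config item, since nothing forces an anatomical layout. Tiling is lossless:
every tile is recoverable bit-exactly from the composite and its tile map.

Time-shift augmentation re-windows each trial +100 and +200 ms (tail
zero-padded when the source recording is unavailable), tripling the
collection; children record their parent and shift, and the split logic
assigns them wherever the parent lands, so no trial and its shifted copies
ever straddle train/validation/test.

## Decoders

Both decoders run on a small numpy neural-network engine written for this
package (dense and valid-mode conv2d layers, ReLU/sigmoid, max pooling,
softmax cross-entropy, SGD and Adam with global-norm gradient clipping,
minibatch training with validation-patience early stopping and
best-validation snapshotting; all randomness flows through a seeded
generator, so training is bit-reproducible single-threaded).

- **Shallow ANN baseline**: 1176 (or 6×channels) → 256 sigmoid → softmax,
  SGD at learning rate 0.01 (tuned over {0.1, 0.01, 0.001, 0.0001}), max
  100 epochs, early stop after 6 validation events without improvement,
  features z-scored with training-set statistics (RMS magnitudes differ by
  orders of magnitude across bands; plain SGD needs comparable scales).
- **Small CNN**: first kernel 11×11 (large initial receptive fields suit
  scalogram energy blobs), stride 2, 16 filters; 3×3/32 block; 64-unit
  dense; 5-way softmax head. Adam at 1e-4 with the head at 20× that rate,
  minibatch 64, max 60 epochs, validation every 6 optimizer steps with
  patience 6 validation events, gradient clipping at global norm 1.0. This
  network trains on one CPU in minutes and follows the same training
  protocol a large pretrained backbone would; swapping in such a backbone is
  an extension point, not a requirement of the analysis.
- **Per-sensor aggregation** (spectral-temporal route): the CNN is trained
  with every sensor's image as an independent sample; a trial's score for
  class k is the mean over sensors of −log p(k), the prediction the argmin
  (geometric-mean probability). Ties break to the lowest class index and are
  flagged. Arithmetic-mean probability is available as an alternative
  aggregator.

## Evaluation protocol

Stratified 70/15/15 train/validation/test splits (largest-remainder
rounding per class), repeated over 3 seeded assignments; accuracy is
summarized as mean ± SD across repeats. The headline accuracy is the mean
of per-class accuracies (classes absent from a test set are excluded);
overall trace/total is reported alongside. One-vs-rest ROC AUCs come from
probability scores with a macro average. The chance level is the exact
binomial inversion: the smallest accuracy k/n with P(Binom(n, 1/K) ≥ k) ≤ α
(α = 0.05 default, capped at 100% when no count qualifies — e.g. n = 1).
At n = 60, K = 5 this gives exactly 30.0%; at n = 300 it gives 24.33%.
Method pairs are compared with paired two-tail t-tests (uncorrected, with
Holm-adjusted p-values reported alongside as a labeled extension), methods
against chance with one-sample one-tail t-tests. Evaluation is
subject-dependent throughout.

## Problem sizes and expected numbers

The shipped study runs at desk scale: 25 channels (5×5 tile grid), 5
classes, 50 trials per class, scalograms on 4×-decimated signals with 32
frequencies and 8×8 tiles. At the default stage SNRs both decoders reach
100% production-stage test accuracy and macro AUC 1.0, while pre-stimulus
accuracy stays inside the chance interval — the synthetic signatures are
cleaner than real cortical activity, so the interesting outputs are the
contrasts (stage ordering, chance calibration, shuffled-label behaviour),
not the absolute accuracy. The full 196-sensor geometry is exercised for
its constants (1176-dim features, 14×14 tiling with zero empty cells,
3× augmentation).

## Known limitations

- The dyadic band edges and printed band labels disagree by design (58–62 Hz
  is unassigned in the printed table; the dyadic filter bank cannot realize
  that gap), and db4 leakage blurs band boundaries.
- The digital Butterworth's response near Nyquist is sharper than the analog
  closed form suggests (bilinear warping); tests verify against the designed
  filter's own transfer function.
- The CNN is intentionally small; no claim is made that it matches the
  capacity of ImageNet-scale backbones.
- Synthetic saturation means accuracy ceilings, not realistic effect sizes;
  real-data accuracies are out of scope by construction.
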