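# Methods

## Synthetic ERD trial model

Each trial is 8 s of 3-channel (C3, Cz, C4) signal at 250 Hz with a cue
at 3 s. Every channel carries a mu (10 Hz) and a beta (22 Hz) sinusoid
with per-trial uniform phases on a white Gaussian background; on the
channel contralateral to the imagined hand (left hand → C4, right hand →
C3) both oscillations are scaled by `1 − erd_depth` during the ERD
window, 0.3–2.8 s after the cue, so attenuation fully covers the
0.5–2.5 s analysis epoch. Cz and the ipsilateral channel are never
attenuated.

Defaults (the "strong effect" fixture): `mu_amp = beta_amp = 1.0`,
`noise_sd = 0.5`, `erd_depth = 0.8`. The classifier experiments use
`noise_sd = 0.3`, giving a clearly decodable but non-trivial effect.
What the generator deliberately omits: 1/f spectral background, the
post-imagery ERS rebound (it falls outside the analysis epoch),
volume conduction, eye/muscle artifacts, and inter-subject variability in
ERD frequency and depth. Noise is white because spectral color is
orthogonal to what the classifier must learn (the lateralized band-power
asymmetry); consequently a passing discriminability test shows that the
pipeline recovers a known contralateral attenuation at a given SNR — not
that it attains any particular accuracy on recorded EEG.

Trials are generated from per-trial substreams spawned off one seed, so
datasets are reproducible and any prefix is independent of the total
count. `band_power` — the test oracle — integrates spectrum-scaled
periodogram power over a band, so a unit in-band sinusoid measures 0.5
(its mean square) and the contralateral/ipsilateral power ratio of a
noiseless trial is `(1 − erd_depth)²`.

## Preprocessing

4–38 Hz band-pass covering mu+beta. The filter family and order are not
dictated by the task, so the package uses standard EEG practice: a
4th-order Butterworth applied forward–backward (zero phase), which
preserves ERD latencies; measured response: −0.001 dB at 20 Hz, −27.5 dB
at 50 Hz. Because the 4/38 Hz cutoffs are −3 dB points, a few percent of
broadband power necessarily survives in the transition skirts; the
filtering contract is therefore checked as stopband leakage (outside
2–45 Hz) below 1% of total output power.

Filtering is applied to the whole trial *before* epoching so edge
transients stay outside the analysis window; the epoch is the half-open
sample range `[cue + round(0.5·fs), cue + round(2.5·fs))` — exactly 500
samples at 250 Hz. Channel order (C3, Cz, C4) is fixed end-to-end;
archives with a different order are rejected, not silently reordered.

## STFT imaging

Hann-tapered frames of 128 samples with overlap 100 (hop 28), one-sided
DFT magnitudes, no boundary padding, trailing partial frame dropped:
`floor((500 − 128)/28) + 1 = 14` frames × 65 bins per channel. The
14 contiguous bins 4–17 (7.81–33.20 Hz at 1.953 Hz spacing) cover mu
(8–12 Hz) and beta (16–31 Hz) and are the only crop width consistent
with the 14×14 image contract. Magnitudes are linear (not log, not
power) and each image is min–max scaled to [0, 1] — matching the
decoder's sigmoid pixel range — with constant images mapping to zeros.
A window length of 140 appears in one description of this pipeline but
is mutually inconsistent with the 65×14 output shape; 128 is the default
and the configuration records whichever value produced an archive.

## Capsule network

Implemented entirely in NumPy with hand-written backpropagation. This
keeps the dependency surface small and the arithmetic transparent; at
these sizes (3200 primary capsules, ~1.3 M parameters) vectorized NumPy
trains 100 epochs on 200 trials in under a minute on one CPU. Gradients
are exact — including through the unrolled routing loop, the squash
nonlinearity and the coupling softmax — and are validated against
central finite differences (64-bit, relative error < 1e-4 at step 1e-5;
observed ~1e-7).

Choices where the architecture description leaves room:

- **PrimaryCaps** is a convolution with `primary_channels × primary_dim`
  = 512 output maps (3×3, stride 2, valid) on the 4×12×12 input, giving
  a 5×5 grid, reshaped to 3200 capsules of dimension 4; squash is
  applied per capsule.
- **Routing weights** W_ij are distinct per (input capsule, class) pair;
  routing logits reset to zero on every forward pass.
- **Decoder**: ReLU hidden layers, sigmoid output so reconstructed
  pixels lie in (0, 1) like the normalized images; masking keeps only
  the true-label capsule during training and the predicted capsule at
  evaluation. Reconstruction loss is the sum of squared pixel
  differences, weighted 0.0005 in the total loss.
- **SELU** constants: scale 1.0507, alpha 1.6733.
- **Initialization**: N(0, 0.1) for routing weights, fan-in-scaled
  Gaussians for convolutions and dense layers, all from one seed.
- **Numerics**: float32 for training, float64 switch for oracle and
  gradient tests. Ties in the class-norm argmax break toward the lower
  index.

## ShallowNet baseline

Temporal convolution (40 × 1×25) → spatial convolution over all three
electrodes (40 × 3×1) → batch norm → squaring → average pool (1×75) →
log (clamped at 1e-6) → dropout 0.5 → dense softmax. The published shape
chain (40×3×476 → … → 1×40×5 → flatten 200) fixes the pool stride at
100, the only value for which `floor((476 − 75)/100) + 1 = 5`; the
dropout rate is unstated upstream and defaults to 0.5. It consumes raw
3×500 epochs and trains under the same SGD loop.

## Training and evaluation

Classical (heavy-ball) momentum SGD: batch 50, learning rate 0.01,
momentum 0.7, 500 epochs by default; the final short batch is used.
Accuracy is 1 − misclassification rate. Early stopping monitors
validation loss (by default the last 20% of training trials, stratified)
and stops when it has not strictly improved for `patience` consecutive
epochs, restoring the best-validation parameters; without early stopping
the final-epoch parameters stand. The grid runner trains every
hyperparameter combination with a shared seed and ranks configurations
by test accuracy, recording invalid combinations (empty capsule grids)
as skipped.

## Problem sizes in the shipped experiments

Tests and the acceptance script use 100 trials per class for training
and 100 per class for held-out evaluation, 100 training epochs, with
`erd_depth = 0.8, noise_sd = 0.3` (strong effect) and `erd_depth = 0`
(null). These sizes give tight Monte-Carlo behavior — the null accuracy
is checked against the central 99% binomial band around 0.5 at n = 200 —
while keeping a full pipeline run to a couple of minutes per model on a
single CPU.

## Known limitations

- Synthetic data only, by design; accuracies on the generator say
  nothing quantitative about recorded EEG (see the generator section).
- Two classes only; EM routing, stacked capsule layers and ensembles are
  out of scope.
- The GDF reader is a thin optional adapter (via `mne`) and assumes the
  3-bipolar-channel, 250 Hz, cue-annotated recording layout.
- Batch norm statistics in ShallowNet make its loss batch-size
  dependent; evaluation uses running statistics.
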