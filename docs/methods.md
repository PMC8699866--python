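# Methods

This note documents the models and procedures implemented in `pcglvdd`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not demonstrate.

## Problem setting

Left-ventricular diastolic dysfunction (LVDD) alters the mechanics of
ventricular filling, and with them the acoustic signature of the second
heart sound (S2): on spectrograms, LVDD-class heart sounds concentrate S2
energy below roughly 150 Hz while normal-diastole recordings reach about
200 Hz. The pipeline screens phonocardiograms (PCG) for this signature:
recordings are denoised and segmented into cardiac states, fixed-length
frames anchored at S1 onsets are converted to log-spectrogram images, the
image corpus is expanded by audio-domain augmentation and a per-class
DCGAN, and a small CNN classifies images as LVDD vs control under
subject-wise cross-validation. Clinical PCG corpora for LVDD are scarce and
private, so the package ships a simulator that generates labelled cohorts
with the same spectral contrast, making every stage testable end to end.

## Synthetic PCG simulator (`pcglvdd.synth`)

Each cardiac cycle is S1 → systole → S2 → diastole. S1 and S2 are
Gaussian-enveloped chirps sweeping downward across a configurable band
(defaults: S1 30–110 Hz over 70–140 ms; S2 50–200 Hz control / 50–150 Hz
LVDD over 50–100 ms), with S1 1.25× louder than S2, the apex-auscultation
convention. Cycle periods jitter cycle-to-cycle (truncated normal, SD 3 %
of the mean period); systole occupies 0.35 of the cycle, a physiological
convention. Cohorts draw per-subject heart rates from N(70, 5) bpm clipped
to 45–120. White Gaussian noise is added at a target SNR over the whole
recording (default 15 dB; ∞ disables it). Defaults: 300 s recordings at
8000 Hz; cohort sizes of 30 LVDD vs 41 control mirror the target clinical
setting. Ground truth (per-sample states, S1 onsets, sound centers) is
returned with each recording.

What the simulator does *not* emulate: murmurs and ejection clicks,
respiration and posture modulation, sensor/contact artefacts, inter-beat
amplitude variability beyond the chirp randomization, and any calibrated
relation between echocardiographic indices and sound morphology. Passing
tests therefore demonstrate algorithmic correctness and sensitivity to the
designed spectral contrast, not clinical performance.

## Preprocessing (`pcglvdd.preprocess`)

Recordings are decimated to 1000 Hz with polyphase anti-aliased resampling
(heart-sound energy lives in 20–200 Hz, so 1000 Hz is comfortably above
Nyquist), wavelet-denoised, and peak-normalized (division by max |S_n|, so
signals map into [−1, 1] even when the largest excursion is negative).
Denoising defaults to Daubechies-6, 5 levels, soft thresholding with a
universal threshold per level; the noise scale is estimated once from the
finest detail level's median absolute deviation (robust to in-band signal)
and the threshold varies per level through its coefficient count. A SURE
threshold and hard thresholding are available through `DenoiseConfig`. An
all-zero signal is returned unchanged by `denoise` and rejected by
`normalize`.

## Segmentation (`pcglvdd.segment`)

A duration-constrained HSMM with logistic-regression emissions. Four
envelope features are computed at 50 Hz on the 1000 Hz signal —
homomorphic envelope (8 Hz low-passed log analytic envelope), Hilbert
envelope, 20–200 Hz band-power envelope, and a wavelet-detail envelope
(db6 level-3 detail, ≈62–125 Hz) — each z-normalized per recording. A
multinomial logistic regression trained on simulator-labelled rows supplies
emission probabilities; per-state Gaussian duration priors are estimated
from labelled run lengths. Decoding is an explicit-duration Viterbi over
the fixed cyclic order with durations limited to mean + 3 SD; the first run
may start anywhere in the cycle and the final run may be truncated (it pays
a duration survival penalty instead of the full Gaussian). The decoded
50 Hz path is upsampled to sample resolution, so detected boundaries are
quantized to 20 ms; the ±20 ms onset tolerance used in tests is exactly one
grid step. Frames are 1.6 s (1600 samples), start at detected S1 onsets,
and successive frames are separated by at least two estimated mean cardiac
periods, read deterministically as "the first onset at least two mean
cycles after the previous frame ends". Coordinates are 0-based with
half-open state runs.

## Spectrogram imaging (`pcglvdd.spectro`)

STFT with a 256-sample periodic Hann window (integer-bin nulls), hop 10,
FFT length 256. A 1600-sample frame yields 135 columns; the central 128 are
kept (the imaging contract fixes the output size but not the hop or crop,
so the deterministic center-crop discards only edge columns). The
one-sided spectrum has 129 bins; the Nyquist bin is dropped, keeping DC and
the whole 20–200 Hz band. The image is log(|S|² + ε) with ε = 1e−10,
min–max scaled per image to [0, 1] (matching how individual image files
would be rendered), and replicated to 3 channels (`colormap` mode exists
for visualisation only). Row 0 is DC. Desk-scale image sizes (32, 64) are
produced by average-pooling the full 128×128 grid, so the whole 0–500 Hz
band — including the class-separating 150–200 Hz region — survives
downsizing; truncating to the lowest bins instead would discard it.

## Augmentation (`pcglvdd.augment`, `pcglvdd.gan`)

Non-generative: five audio-domain techniques per frame — pitch shift ±2
semitones (polyphase resample then phase-vocoder stretch back), time
stretch at 0.9 and 1.1 (phase vocoder, 256-point FFT, hop 64), and silence
trimming at −40 dB relative to peak — each refitted to exactly 1600 samples
by center-crop or reflection padding. Exactly five augmented images per
frame; originals are not counted.

DCGAN: the generator maps a 100-dim latent vector through a dense
projection to 8×8×512 (a stride-2 5×5 transposed convolution cannot map
1×1×100 to 8×8×512, so the projection is implemented densely, the standard
DCGAN construction) and four 5×5/stride-2 transposed convolutions halving
channels to a 128×128×3 Tanh output; batch normalization and ReLU follow
every stage except the output. The discriminator mirrors with five
5×5/stride-2 convolutions (64→1024 channels), batch normalization on every
convolution, Leaky ReLU slope 0.2, and a dense sigmoid scalar with no
batch normalization (normalizing a 1-unit output is degenerate). Training
alternates a generator step and a discriminator step per batch with Adam
(lr 2e−4, β₁ 0.5, batch 64, 300 epochs at full scale); real images are
mapped to [−1, 1]. Both steps pass a combined real+fake batch through the
discriminator so its batch-norm statistics are consistent between steps and
meaningful at inference. The generator loss is the non-saturating
cross-entropy −E log D(G(z)) by default; the strict minimax form is a
config option. Labels are real = 1, fake = 0 without smoothing. One GAN is
trained per class, and generated images carry that class label. Smaller
image sizes for desk-scale work drop leading up-sampling stages (32×32
starts from a 4×4 projection, three stages) and may narrow `base_channels`
while keeping the channel-halving pattern.

The whole network stack is a small NumPy layer library (`pcglvdd.nn`):
im2col convolution, adjoint-based transposed convolution, batch norm,
max-pooling, dropout, Adam. Every layer's backward pass is verified against
numerical differentiation in the test suite, and training is deterministic
for a fixed seed on single-threaded BLAS.

## Classification and validation (`pcglvdd.classify`)

The classifier is three 3×3/stride-1 conv + ReLU + 2×2/stride-2 max-pool
blocks with 64, 32 and 16 channels, a row-major flatten of the 16×16×16
tensor, fully connected layers of 128 and 100 units (no intermediate
activation — the reference architecture specifies none), dropout 0.5
after the second, and a two-class softmax. Adam at 1e−4; 500 epochs and
batch 64 at full scale (the batch size is an open choice; 64 matches the
GAN); no early stopping by default, though `stop_at_val_accuracy` can end
training once a validation target is reached. Direct parameter count of
this reading is 562,398; the published total for the reference
architecture (559,396) is close but not reproducible from the stated
shapes, so the computed count is reported instead. Ties at
probability 0.5 go to the control class for determinism.

Cross-validation is subject-wise: subjects are partitioned into k = 10
folds greedily by sample count, stratified by class; repetitions rotate the
test fold, with the validation fold next in cyclic order. Augmented images
inherit their source frame's subject and must not fall in evaluation folds
(a violation raises a leakage error); per-class GAN images have no source
subject and join training folds only. Metrics are accuracy, sensitivity
and specificity from the test fold's confusion counts (LVDD positive),
reported as mean ± SD over repetitions; degenerate denominators raise
rather than return a silent 0.

## Evaluation protocols (`pcglvdd.evaluate`)

TSTR: a classifier trained only on generated images (both classes) is
tested on real images; its test accuracy is the similarity score. A
repeated-run mean is supported (the repetition count is a free choice;
default 1, with multi-seed averaging used in tests). The expansion sweep
reruns cross-validation with k generated images per real image for each
coefficient k. The summary t-test reproduces group p-values from printed
mean/SD/n triples; the pooled-variance (Student) form is the default
because it reproduces the printed E-wave p = 0.034 exactly (the Welch form
does not); Welch is a flag. One printed row (A-wave, p = 0.589) differs
from the pooled-summary computation (≈0.587), consistent with the original
value having been computed on unrounded raw data. Reports are written as
sorted-keys JSON (byte-reproducible) plus a flattened CSV.

## Desk scales used by the test suite

The full 128×128 models are built and shape-checked layer by layer, and
the classifier criterion trains the full-width 128×128 CNN (stopping once
the validation target is reached within the 50-epoch cap). Training-heavy
properties (GAN equilibrium, TSTR) run at 32×32 with narrowed channels
(8–16 base), 100–200 images per class and 120–200 epochs; segmentation
recovery uses ten 30 s clean recordings. These sizes were chosen so the
whole suite runs in minutes on one CPU while keeping every qualitative
property of the full-scale configuration.

## Known limitations

- The pipeline smoke profile (4 + 4 subjects, 30 s recordings, 32×32
  images, reduced epochs) is an end-to-end plumbing check, not a
  performance claim: with only four training subjects per fold the CNN
  often fails to isolate the modest spectral contrast that a linear probe
  on the same images finds (leave-one-subject-out ≈ 0.86), and subject-wise
  CV accuracy is correspondingly noisy. Capability-level evidence comes
  from the dedicated tests at their stated scales.
- The wavelet denoiser is a standard shrinkage scheme standing in for an
  "improved" variant whose reference is not reproducible; it is
  configurable but not tuned to clinical recordings.
- Segmentation boundaries are quantized to the 20 ms feature grid.
- The simulator's amplitude statistics are not calibrated to clinical
  data; simulator-trained components should be retrained on labelled real
  recordings before any clinical use.
- TSTR on strongly clustered synthetic classes is bimodal per seed (a
  noise-trained classifier maps whole clusters to one side); chance-level
  behaviour emerges only as a multi-seed average.
- The exact hop, color rendering, augmentation magnitudes and TSTR
  repetition count of the original study are unstated; the defaults here
  are documented choices, not inferred intent.
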