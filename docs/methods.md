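# Methods

`dryeeg` implements an automated *clean* versus *artifact* classifier for
single-channel dry-electrode EEG, together with the full preparation and
evaluation pipeline around it and a synthetic data generator that stands in
for real recordings. This note records the model, the parameter choices that
matter, and the places where the design was genuinely open.

## Signal preparation

Raw recordings are 8-electrode dry-cap EEG (FC3, FC4, CP3, CP4, FT7, FT8,
TP7, TP8) sampled at 500 Hz in microvolts. Preparation runs in four stages,
in this order:

1. **Bipolar montage.** Each output channel is the samplewise difference of
   an (anode, cathode) electrode pair. The default montage takes all
   C(4,2) = 6 within-hemisphere pairs per hemisphere, 12 channels total —
   the only combinatorially consistent reading of "six bipolar channels per
   hemisphere" from four electrodes; any montage can be supplied instead.
2. **Bandpass 0.5–35 Hz**, 3rd-order Butterworth. The filter is applied
   forward–backward (zero phase) so that sample-wise annotations stay
   time-aligned with the filtered signal; this doubles the effective order.
   A causal mode is available behind `PreprocessConfig(zero_phase=False)`.
3. **Downsample to 100 Hz** by polyphase resampling with linear-extension
   padding. The anti-alias filter is redundant given the 35 Hz low-pass but
   keeps the stage safe under configuration changes.
4. **Clip at ±800 µV**, removing non-physiological excursions (electrode
   pops reach ±1500 µV before this stage). Clipping is idempotent.

The pipeline records applied stages on the recording object and skips the
non-repeatable ones (montage, downsample) if fed an already-processed input.

## Annotation model and soft labels

Three to four reviewers annotate every bipolar channel sample-wise as
*clean*, *clean with a high-frequency (HF) component*, or *artifact*,
including margins of at most 0.5 s around visible artifacts. The HF class is
resolved automatically: a sample becomes *clean* when the RMS of the
25–35 Hz band-limited signal in a centred 1-s window is below 10 µV, else
*artifact*. The band, window and threshold are declared interpretations of
"small" versus "large" HF component (the underlying quantitative criterion
is not public) and are fully configurable via `HFRule`.

Resolved votes aggregate to a per-sample **soft label** = (#clean votes) /
(#votes cast); samples nobody annotated are missing and any window touching
them is dropped. Inter-rater agreement is Fleiss' kappa computed per
constant-reviewer-count block (3-reviewer and 4-reviewer data separately,
the statistic requires a fixed rater count) and combined as a
sample-count-weighted average. By default kappa is computed on the
three-category labels as annotated, before HF resolution; a flag computes it
on resolved binary labels instead.

## Segmentation and splits

Channels are cut into 2-s windows (200 samples) with 1.9-s overlap (10-sample
stride); window arithmetic is integer-sample to avoid float drift, and
trailing partial windows are discarded (fixed-length network input). Each
window's label is the mean soft label of its samples; the binary evaluation
label is clean iff soft ≥ 2/3 (inclusive).

The train/test split assigns whole subjects (all sessions of a subject land
on one side), approaching the 20% test fraction as closely as subject
granularity allows, deterministically in the seed. Cross-validation uses
stratified 3-fold splitting on the binarized label; folds are segment-level
(stratification needs a discrete key and subject-disjointness is reserved
for the train/test boundary), with a subject-wise mode behind a flag.
Because neighbouring windows overlap by 95%, training uses every 5th train
segment by default (`train_decimation`); validation, calibration and test
always use the full sets.

## The classifier

A compact 1-D CNN maps a 200-sample window to a clean probability:
three convolution blocks (kernel 7; widths 16/32/64; each block is
convolution → ReLU → batch normalisation → max-pool 2), global average
pooling, a 64-unit dense layer, and a single logistic output. ~22.6k
parameters. Inputs are scaled by a fixed 100 µV constant — amplitude carries
most of the artifact signal, so per-segment standardisation would be
destructive. The network, its backpropagation, AdamW (decoupled weight decay
0.01, applied to connection weights only) and the cosine-annealed learning
rate (initial 0.001, period = max epochs, no restarts) are implemented
directly in NumPy (`dryeeg.nn`); training is exactly reproducible given a
seed.

The loss is binary cross-entropy against the *soft* labels — the fraction of
reviewers voting clean is a meaningful continuous target, and BCE reduces to
the standard form when targets are 0/1. A flag trains on binarized targets
instead. Early stopping halts training when the validation loss has set no
new strict minimum for 10 consecutive epochs; the best-epoch weights are
restored.

**Transfer learning.** A source-domain model is first trained on synthetic
"wet-electrode-like" data (no low-frequency power boost, contact artifacts
at 30% of the dry rates, hard labels — stand-in for a large public wet-EEG
artifact corpus, which carries expert rather than multi-reviewer labels).
Fine-tuning re-initialises the final dense layer from scratch and continues
training *all* layers on the dry-electrode target domain ("last layer" is
read as the output layer only).

**Calibration and ensembling.** Each of the three fold models gets its own
operating threshold, selected on that model's validation fold as the maximum
recall subject to precision ≥ 90% (clean = positive class). Candidate
thresholds are the distinct observed scores plus sentinels — optimal
operating points lie at score order statistics — with ties broken toward
higher precision, then lower threshold. If the floor is unattainable the
calibration fails loudly, carrying the best attainable precision, rather
than silently relaxing. The final classifier is the majority vote of the
three thresholded CNNs. Metrics are reported with clean as positive:
accuracy, precision, recall, specificity, F1; ratios with empty denominators
are reported as missing, never as zero.

## Synthetic data generator

The generator emulates the features of dry-electrode EEG that the pipeline
depends on, not the biophysics:

- **Background**: white noise shaped in the frequency domain to a 1/f^β
  spectrum (β = 1.5), a Gaussian alpha ridge at 10 Hz (power ratio 2), and a
  ×1.6 power boost below 6 Hz — the dry-electrode signature; RMS 15 µV.
  Electrode signals mix three shared "cortical" sources with per-electrode
  noise so bipolar derivations neither vanish nor duplicate.
- **Artifacts** as independent Poisson event streams per type, with
  waveform families and amplitude/duration ranges chosen for realistic
  dynamic range: blink (smooth monophasic 100–300 µV, 0.2–0.5 s, frontal),
  eye movement (ramp/plateau 50–150 µV, frontal), muscle (20–100 Hz burst,
  30–100 µV RMS, temporal), electrode pop (step + exponential decay up to
  ±1500 µV — deliberately beyond the clip limit), cable movement (slow
  < 4 Hz oscillation 200–600 µV), and impedance (sustained broadband noise
  plus drift). Default rates (blink 6, eye movement 3, muscle 5, pop 1.5,
  cable 1.5, impedance 0.8 events/min) emulate an induced-artifact protocol
  and put segment-level prevalence near 40% artifact / 60% clean, the regime
  the method is meant for. Overlapping events union in the ground-truth mask.
- **Reviewers**: each simulated reviewer reproduces the true events with the
  boundary-margin convention — every event edge extended *outward* by an
  independent uniform jitter up to 0.25 s (trained reviewers include
  margins, never crop; the 0.5-s bound is enforced) — flips isolated
  clean/artifact samples with probability 0.01, and tags muscle events as
  *clean-with-HF* with probability 0.5. Sessions alternate 3 and 4
  reviewers. These defaults land the weighted Fleiss' kappa near 0.75,
  the same substantial-agreement regime as trained human reviewers.

What the generator does **not** model: volume conduction and head geometry,
cardiac/respiratory/sweat artifacts, non-stationary background (sleep
stages, eyes open/closed), reviewer-specific biases, or inter-subject
spectral variability beyond the seeded source mixing. Passing the end-to-end
tests therefore demonstrates that the pipeline machinery — labeling,
training, calibration, voting — recovers a recoverable signal; it does not
certify performance on clinical recordings.

## Problem sizes and numerical choices

The default end-to-end study simulates 10 subjects × 60-s sessions
(≈ 70k segments; ~11k training segments after decimation, ~14k test
segments from 2 held-out subjects), pretrains for up to 20 epochs on a
4-subject source domain, and fine-tunes each fold for up to 30 epochs with
patience 10 — sizes chosen so a full run completes in minutes on one CPU
while every stage operates well inside its asymptotic regime. Comparisons
against the 2/3 soft-label boundary use exact floating-point ≥ on the
rational 2/3. The seeded stage-offset scheme (`pipeline.stage_seed`) expands
one global seed into per-stage seeds below 2³¹, so stages can be reproduced
in isolation.

## Known limitations

- The CNN architecture is a declared substitution: the original study's
  exact layer structure is not public, and its pre-trained wet-EEG weights
  are replaced by synthetic source-domain pretraining. Headline numbers from
  real dry-electrode data (accuracy ≈ 0.91, kappa 0.70) are context, not
  reproduction targets of this package.
- Boundary windows around artifact edges have genuinely ambiguous labels
  under reviewer jitter: a window whose artifact coverage sits near 1/3 of
  its length gets its binary label decided by the margin realization. On the
  default synthetic study a fixed-margin oracle that knows the true event
  times scores ≈ 94.5% against the reviewer-derived labels and the Bayes
  rule ≈ 96%; the CNN ensemble itself lands at 90–92% — the same regime the
  method reaches on real dry-electrode data — with its errors concentrated
  in windows whose segment soft label falls between 0.55 and 0.78. Training
  longer, on less-decimated (more strongly overlapping) data, or with wider
  or finer-grained architectures did not move test-subject accuracy by more
  than a fraction of a percent.
- The EDF writer is minimal (16-bit, 1-s records, zero-padded tail); it
  targets interchange within this pipeline, not full EDF+ compliance
  (no annotations channel, single patient field).
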