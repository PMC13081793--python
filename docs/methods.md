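# Methods

This note documents the models and procedures implemented in `marinesed`,
the parameter defaults and why they were chosen, what the synthetic data
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## 1. Synthetic call corpus (`fixtures`)

Four parametric archetypes stand in for single-species call segments.
Each is band-limited by an rfft brick-wall mask to its nominal band,
amplitude-enveloped with a randomized 10–30 % fade, and normalized to unit
RMS. Durations are drawn uniformly from 1.0–2.0 s (segments shorter than
1 s carry too little spectral information to be useful).

| archetype | band (Hz) | structure | emulates |
|---|---|---|---|
| `fm_sweep` | 100–400 | linear FM sweep, random direction | bowhead whale moan |
| `harmonic_song` | 200–2000 | fundamental + 3 harmonics, slow vibrato | humpback song unit |
| `pulse_train` | 500–2000 | 70 ms damped knocks at 12 s⁻¹, one pitch per call | walrus knock train |
| `click_train` | 2000–10000 | 45 ms noise bursts at 15 s⁻¹, per-call ~1.5 kHz sub-band | sperm whale click packet |

Design notes:

- **Per-call spectral stability.** Knock pitch and click sub-band are drawn
  once per call, not per pulse. Real pulsed calls keep a stable spectral
  character within a call; a frequency-hopping stand-in would also make the
  energy in any one frequency bin too transient for threshold-based
  annotation of sustained energy, which is the annotation model's premise.
- **Duty cycle.** Pulse/burst envelopes are long relative to their periods
  (≈ 70–85 %). The annotation search compares each bin's *temporal mean*
  magnitude against a robust threshold; call types whose energy is
  vanishingly sparse in time are invisible to that statistic by design, so
  the corpus emulates calls with sustained in-band energy.
- **Recording structure.** Segments of one class are spread round-robin
  over n "recordings"; each recording carries a ±5 % band jitter so that
  segments within a recording are more alike — this is what makes the
  grouped train/test split meaningful.
- Resampling is polyphase (anti-aliased), `scipy.signal.resample_poly`,
  with the ratio approximated to denominator ≤ 1000. The standard rate is
  40 kHz. RMS normalization targets 1.0; any fixed constant works since
  mixing re-normalizes.

## 2. Mixture construction (`mixer`)

A monitoring sample is a 5.0-s window. Modes:

- **nonoverlap** — 2–4 events of distinct classes laid out sequentially
  with uniform random gaps of 0.05–0.3 s and a random global offset; plans
  that cannot fit retry with fewer events (failing below two).
- **overlap** — 2–4 events of distinct classes with uniform random starts,
  accepted only when (a) instantaneous concurrency (sweep-line over
  endpoints; touching intervals do not count) never exceeds the cap
  (default 2, relaxable to 3/4 for the density experiment) and (b) at
  least one pair genuinely overlaps, so "overlap" samples never silently
  degenerate to sequential ones. Rejection sampling has a budget of 100
  tries per plan.
- **single_class** — exactly one event, uniformly placed; used as an
  auxiliary training set that isolates one species per sample.

Noise: standard-normal noise over the full window is rescaled to
`RMS_noise = RMS_clean / 10^(SNR/20)` with SNR_target = 4 dB by default,
added, and the result is RMS-normalized to 1. Because the noise is rescaled
to the *measured* target RMS, the realized SNR equals the target exactly
(to floating-point precision), and it is invariant under the final
normalization since that scales clean and noise components together.

Default dataset sizes are 300 train / 100 test mixtures per mode at desk
scale (configurable); per-sample seeds derive deterministically from one
master seed.

## 3. Spectrograms (`spectro`)

STFT with N = 1024, R = 256, periodic Hann window, reflect center padding
(N/2 per side) so events at window edges receive full frames: a 5-s sample
gives 513 × 782. dB conversion is 20·log10(mag/max) floored at −80 dB. The
dB reference is per-spectrogram; every downstream statistic (median, MAD,
threshold) is translation-equivariant on the same matrix, so the reference
choice cannot affect which bins are selected. The frequency axis is linear,
0 to Nyquist (20 kHz).

## 4. Automated annotation (`annotate`)

Background = median of the whole dB matrix (robust to the high-energy
event cells). Threshold = background + max(3 dB, 2.5·MAD), MAD computed on
the same dB matrix — both candidate margins live on the dB scale so the
max() is well defined. For each event the temporal bounds come verbatim
from the mixture manifest; within those frames the per-bin temporal mean is
scanned upward from 0 Hz and downward from Nyquist, stopping at the first
bin above threshold. Events with no bin above threshold are logged and
*dropped* — a fabricated full-band box would poison training. On the
default corpus this affects well under 1 % of events (sparse click trains
in unlucky noise draws).

For overlapping mixtures, mixed energy makes per-event thresholding
unreliable; each event instead gets its class's mean measured box height,
centered at the class's mean center frequency (the center rule is needed to
place a box and the symmetric choice is the natural one), truncated to
[0, Nyquist]. Class statistics come from a dedicated batch of
non-overlapping mixtures rendered from the same corpus partition.

YOLO serialization normalizes continuous frame/bin coordinates to [0, 1]
with image row 0 at Nyquist (top of a rendered spectrogram); write→read
round-trips to within one frame/bin.

## 5. CutMix (`augment`)

One annotated event rectangle is cropped from a donor spectrogram and
pasted into a base at a uniform random time offset (fully inside the
image), *replacing* base values; the donor's label is appended with only
its times shifted. Vertical shifts are deliberately forbidden — moving a
call out of its species' band would fabricate biologically implausible
data while the network still learns frequency structure implicitly. The
paste may overlap existing base events and the concurrency cap is *not*
re-applied; overlap exposure is the augmentation's purpose. Default
application probability per training sample: 0.5. No label-area mixing
(the pasted event is one full additional object). Applied to training
data only.

## 6. Detector (`model`, `detector`, `nn`)

**Input.** The 513 × 782 dB matrix is block-mean downsampled to 96 × 256
and affinely mapped to ≈[−1, 1]. Frequency bins become the input channels
of a 1-D (time-axis) convolutional network — the natural formulation when
heads predict only temporal boundaries.

**Architecture.** Stem (stride 2) plus three stages (stride 2 each) give
feature maps at strides 4/8/16 along time with 32/48/64 channels, each
refined by a C2f block (input projection split into a bypass branch and a
residual-bottleneck branch, concatenated, fused 1×1). A top-down FPN path
(nearest ×2 upsampling + concat + C2f) and a bottom-up PAN path (stride-2
conv + concat + C2f) fuse scales. Per-scale heads output, per time cell:
1 objectness logit, 4 class logits, a center offset (tanh, ±64 input
frames) and a log-width (relative to the cell stride). All convolutions
are conv → per-channel instance norm (statistics over time, no running
averages, so inference is deterministic) → SiLU.

**Targets and loss.** Each ground-truth event is assigned to the scale
whose cell width best matches its duration (min |log(width/stride)|);
positive cells are those whose center time falls inside the event.
Loss = 1.0 · weighted objectness BCE over all cells (positive cells
weighted 4×) + 2.5 · class BCE on positive cells + 2.0 · box loss on
positive cells, where the box loss is mean(1 − IoU) between predicted and
target intervals plus a normalized quadratic center term that keeps a
gradient when intervals are disjoint.

**Engine.** The network runs on a small reverse-mode autodiff engine over
numpy float64 arrays (strided conv1d via im2col, hand-derived backward
passes, all verified by finite differences in the test suite) with AdamW
(decoupled weight decay).

**Training.** Full-scale defaults follow standard practice for this model
class: batch 16, up to 300 epochs, early stopping on validation loss with
patience 10, constant learning rate 5e-4, weight decay 5e-4, five folds.
Each fold's model keeps its best-validation checkpoint. The **desk-scale
profile** (`pipeline.desk_scale_train_config`) used by the example runs and
the end-to-end test compresses this to ≤ 20 epochs at learning rate 6e-3
with three folds — at a few hundred training samples on one CPU the shorter
schedule with a proportionally larger step reaches stable ensembles in
minutes. The ensemble averages the per-model prediction maps (objectness
and class probabilities, box center/width in seconds) elementwise; the
averaged map is then decoded and NMS-filtered.

Only the small from-scratch backbone is provided: pretrained image
backbones require network weight downloads and a heavyweight DL runtime,
and the package is designed to build and test fully offline.

**Splits.** The corpus is split 60:40 per class with whole recordings
assigned to one side (greedy, in seeded shuffled order, adding a recording
to train only if that moves the class's train share closer to 60 %);
single-recording classes go wholly to train with a warning. Train and test
mixtures are rendered exclusively from their own partitions, so no segment
(nor recording) crosses sides.

## 7. Evaluation (`evaluate`)

Greedy confidence-ordered one-to-one matching; a true positive requires
class equality and temporal IoU ≥ 0.5; ties in confidence break by earlier
start then lower class id, making results order-independent. Degenerate
denominators yield 0 with a log note (never NaN). Macro metrics are
unweighted means over the four classes; micro metrics come from pooled
TP/FP/FN. The threshold sweep re-filters *raw* (pre-NMS) detections at
each threshold (default 0.2/0.3/0.4), re-runs NMS and matching. The
overlap-density experiment regenerates equally sized overlap datasets at
caps 2/3/4 (their composition necessarily differs stochastically across
caps) and reports macro/micro F per cap.

## 8. What the synthetic data does not show

- No propagation physics: no frequency-dependent attenuation, multipath,
  or refraction; noise is white Gaussian, not a natural soundscape.
- Train and test mixtures share the generator's assumptions (same SNR,
  noise model, overlap statistics); evaluation is in-distribution, and
  scores on it are optimistic relative to field recordings.
- Archetypes are spectrally well separated by construction; real
  congeneric call repertoires overlap far more. Passing the end-to-end
  test demonstrates the pipeline learns and localizes under its stated
  conditions, not field-ready accuracy.
- The annotation thresholds (3 dB, 2.5·MAD) are tuned to this noise
  model; datasets with different SNR regimes will need recalibration.

## 9. Numerical details and scale choices

- All audio/NN math in float64; realized SNR is exact to ≈1e-12 dB.
- Desk-scale problem sizes used by the shipped tests and examples:
  corpus 24 segments/class over 6 recordings; 300 train / 100 test
  mixtures; ≤ 20 epochs; 3 folds. The end-to-end suite run finishes in
  about three minutes on one CPU and reaches macro F ≥ 0.8 (typically
  0.85–0.92 across seeds).
- NMS and matching tie-breaks are fully deterministic; every stage seed
  derives from the master seed via CRC-tagged `SeedSequence`s, so a run
  directory is reconstructible from its resolved `config.yaml` alone.
- Unmatchable annotation events (sub-threshold) are dropped from both
  training and evaluation ground truth, consistently on both sides.
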