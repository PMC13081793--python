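# marinesed

Synthetic marine soundscape construction and YOLO-style temporal detection
of species vocalizations in spectrograms.

Passive acoustic monitoring of marine mammals needs detectors that can
localize and classify *multiple, possibly overlapping* calls inside a
recording — but open archives mostly contain isolated single-species
segments. `marinesed` addresses this the way recent bioacoustic detection
studies do: it **synthesizes annotated monitoring samples** by mixing
single-species call segments into fixed 5-second windows under controlled
noise, **auto-annotates** them on the raw STFT matrix, **augments** with an
object-level CutMix, trains a **single-stage temporal detector** (multi-scale
CNN backbone, FPN/PAN fusion with C2f blocks, 1-D anchor-free heads) as a
k-fold ensemble, and **evaluates** with temporal-IoU matched
precision/recall/F-scores.

It is aimed at bioacousticians and ML researchers prototyping spectrogram
event detectors without access to continuous annotated recordings. Because
this package must run self-contained, single-species segments come from a
seeded parametric generator with four spectrally distinct call archetypes
(low FM sweep, harmonic song, pulse train, click train) emulating the vocal
characters of bowhead whale, humpback whale, walrus and sperm whale; real
WAV segments can be substituted anywhere a `CallCorpus` is accepted.

## The model

**Mixing.** Call segments (resampled to 40 kHz, RMS-normalized) are placed
in a 5-s window — disjoint with small random gaps, overlapping under a
strict concurrency cap (default 2), or as a single event. Gaussian noise
`n ~ N(0, 1)` is rescaled so that

```
20 log10(RMS_clean / RMS_noise) = SNR_target        (default 4 dB)
```

and the noisy mixture is RMS-normalized to 1. Event times are recorded as
ground truth.

**Spectrograms.** `X[k, m] = Σ_n x[n + mR] w[n] e^{-j2πkn/N}` with
N = 1024, hop R = 256, Hann window; magnitudes in dB re the matrix maximum,
floored at −80 dB (513 bins × 782 frames per 5-s sample).

**Automated annotation.** Background = median of the dB matrix; detection
threshold = background + max(3 dB, 2.5·MAD). Within each event's known time
span, a bidirectional search along the frequency axis (up from 0 Hz, down
from Nyquist) stops at the first bin whose temporal-mean magnitude exceeds
the threshold, giving the box's frequency bounds. Overlapping events, whose
energy regions mix, instead receive their species' mean box height/center
estimated from non-overlapping samples. Boxes serialize to YOLO text lines.

**Detection.** Per time cell and scale the network predicts objectness,
class scores, and a temporal box (tanh-bounded center offset, log-width).
Confidence = objectness × best class score; decoding applies a confidence
threshold (0.5 non-overlap / 0.3 overlap) and class-aware greedy NMS at
50 % temporal IoU. A detection is a true positive when it matches an
unmatched ground-truth event of the same class with IoU ≥ 0.5; per-class
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F = 2PR/(P+R)`, with unweighted macro
and pooled micro averages.

## Worked example

```python
from marinesed.fixtures import gen_corpus
from marinesed.mixer import plan_nonoverlap, render
from marinesed.spectro import stft_spectrogram, to_db
from marinesed.annotate import annotate_nonoverlap

corpus = gen_corpus(n_per_class=12, n_recordings_per_class=3, seed=0)
class_map = {name: i for i, name in enumerate(corpus.classes)}

manifest = plan_nonoverlap(corpus, rng_seed=11)
mix = render(manifest, corpus, rng_seed=11)
spec = to_db(stft_spectrogram(mix.waveform))
ann = annotate_nonoverlap(spec, manifest, class_map)
```

prints (via the repository's `scratch`-style driver):

```
events: [('fm_sweep', 0.29, 1.84), ('click_train', 1.9, 3.31)]
realized SNR: 4.000000 dB, concurrency: 1
spectrogram: 513 bins x 782 frames
box class=0 t=[0.29, 1.84] s f=[156, 391] Hz (measured)
box class=3 t=[1.90, 3.31] s f=[5234, 6680] Hz (measured)
```

The two planted events were recovered with measured frequency bounds: the
FM sweep sits in its 100–400 Hz band, the click train around its per-call
sub-band near 5–7 kHz, and the realized SNR equals the 4-dB target exactly
by construction.

A full pipeline run (corpus → mixtures → annotation → CutMix → 3-fold
ensemble → metrics) is one command:

```bash
marinesed run-all --seed 1 --out runs/demo
```

which writes the corpus manifest, mixture WAV + JSONL manifests, YOLO
annotation files, per-fold loss CSVs and checkpoints, and per-species
metrics tables. At desk scale (300 train / 100 test non-overlapping
mixtures, ≤ 20 epochs on one CPU) the ensemble reaches macro F ≈ 0.85–0.92
on held-out synthetic data; `marinesed density` runs the overlap-density
experiment (concurrency caps 2/3/4).

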