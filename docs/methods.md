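# Methods

This note documents the models and procedures implemented in `ecgkit`,
the parameter choices that matter, and what the synthetic test harness
does and does not demonstrate.

## Problem setting

Single-lead ambulatory ECG sampled at 360 Hz, with per-beat annotations
marking the R peak and a beat symbol. The toolkit addresses two linked
tasks:

1. **Denoising**: compare six classical filters on noisy ECG and rank
   them by peak signal-to-noise ratio (PSNR) against the clean
   reference.
2. **Beat classification**: segment annotated beats into fixed-length
   windows, normalize, and classify normal vs abnormal with 1-D
   convolutional networks.

## Record I/O

Records use the WFDB-style layout: a text header, a format-212 binary
signal file (two signed 12-bit samples packed in three bytes,
channel-interleaved), and amplitudes recovered as
`(adc − baseline) / gain` mV. Annotations travel as a plain
`sample_index,symbol` CSV rather than a binary annotation file: the CSV
is lossless for our purposes and keeps every artifact inspectable with
a text editor. Writing quantizes amplitudes to the ADC grid, so a
write/read roundtrip is exact to half an ADC step (`0.5/gain` mV);
amplitudes outside the 12-bit range raise rather than wrap. All sample
indices are 0-based. Multi-channel records are supported at the I/O
layer; downstream stages operate on one selected channel (default 0,
the conventional modified-lead-II position).

## Synthetic ECG generator

The generator is the test harness for every downstream stage; it
emulates the statistical shape of an annotated ambulatory recording,
not cardiac electrophysiology.

- **Beat model**: a sum of five Gaussian bumps (P, Q, R, S, T) with
  amplitudes in mV, centers in seconds relative to the R peak, and
  widths in seconds. The R bump must dominate in absolute amplitude so
  the annotation lands on a local extremum. The default abnormal beat
  is ventricular-like: essentially absent P, a QRS roughly 2.5× wider,
  and an inverted T. These defaults make the two classes separable by
  morphology, which is what the classifier tests require.
- **Rhythm**: RR intervals are i.i.d. Gaussian with configurable mean
  heart rate (default 72 bpm) and coefficient of variation (default
  0.05), truncated at ±3 SD to avoid collisions. Generation fails
  explicitly if beat morphologies would overlap by more than half an RR
  interval.
- **Noise**: additive white Gaussian noise rescaled by its realized
  power so the achieved SNR equals the target exactly (default 10 dB),
  plus optional deterministic sinusoids for baseline wander and 50/60 Hz
  powerline interference. A single integer seed fixes the realization.

What this harness does **not** model: real muscle artifact and
electrode-motion noise (non-stationary, non-Gaussian), beat-to-beat
morphology variability, rhythm abnormalities (the abnormality here is
purely morphological), and multi-lead correlation structure. Passing
tests therefore demonstrate that the pipeline's machinery is correct
and that the procedures behave as designed under controlled conditions
— not that any particular accuracy carries over to clinical recordings.

## Denoising filters

Six filters behind one dispatch interface. Stated defaults apply at
360 Hz; all are config-exposed.

| Filter | Defaults | Notes |
| --- | --- | --- |
| Median | window 5 | nonlinear; removes impulse noise |
| Gaussian | σ = 2 samples, truncate 4 SD | normalized discrete kernel |
| Moving average | window 5 | low-pass FIR |
| Savitzky–Golay | window 25, polyorder 7 | least-squares local fit |
| Butterworth low-pass | order 4, cutoff 40 Hz, zero-phase | forward–backward by default |
| Wavelet | sym8, 4 levels, soft threshold, BayesShrink | see below |

Windowed filters use reflecting edges: edge transients would otherwise
dominate PSNR comparisons on short records. The Savitzky–Golay filter
instead handles edges by evaluating the polynomial fitted to the
first/last full window (SciPy's ``interp`` mode), which preserves its
defining property — signals of degree ≤ polyorder are reproduced
exactly, including at the edges.
Zero-phase Butterworth is the default because offline denoising has no
causality constraint; a flag selects single-pass.

**Wavelet shrinkage.** Multilevel DWT with the sym8 symlet (symmetric
signal extension). The noise SD is estimated from the finest detail
subband as σ̂ = median(|d₁|)/0.6745. Each detail subband receives the
BayesShrink threshold T = σ̂²/σ̂ₓ with σ̂ₓ = √max(var(d) − σ̂², 0); a
subband whose variance does not exceed σ̂² is indistinguishable from
pure noise and is zeroed (T set to its largest coefficient). Soft
thresholding in an orthonormal basis is non-expansive, which the tests
assert directly.

**PSNR.** `10·log₁₀((L−1)²/MSE)`. The intensity-level count L is a
quantized-signal concept; for real-valued ECG, `L − 1` defaults to the
dynamic range (max − min) of the clean reference, overridable. The
benchmark reports each filter's mean PSNR over seeded noisy records,
sorted ascending, with a no-op baseline row (the noisy signal itself).
The interesting output is the ranking and the margin over the baseline;
absolute PSNR depends on the noise level and the reference dynamic
range.

## Preprocessing

- **Segmentation**: one window per annotation, 2160 samples (6 s at
  360 Hz), centered on the annotated R peak (1080 samples either side).
  Windows that would cross a record boundary are dropped and counted.
  At normal heart rates 6-second windows of adjacent beats necessarily
  overlap; this is accepted — each window is a beat-centered context,
  not a disjoint partition of the record.
- **Normalization**: per-segment Z-score with population SD, removing
  amplitude scaling and offset. Constant segments (SD < 1e-12) map to
  zeros with a warning instead of dividing by ~0.
- **Labels**: binary; symbol `N` → 0, every other *beat* symbol → 1.
  Non-beat symbols (rhythm and quality markers such as `+`, `~`) are
  excluded together with their windows. Unknown symbols are excluded by
  default; a strict mode raises.
- **Split**: segments are shuffled and divided 80/20, stratified by
  label (per stratum `round(0.8·n)` to train), so both classes appear
  in the held-out set even under class imbalance. Single-class input
  falls back to a plain shuffled split with a warning. The split is
  per-beat, not per-record.

## Architectures

Three fixed 1-D CNNs on (2160, 1) inputs, each a stack of
Conv1D(ReLU) → Dropout → MaxPool(pool 2, stride 2) blocks followed by a
flatten and a sigmoid head. Convolutions are unpadded ("valid", output
length N − K + 1) and pooled lengths round down; with this convention
the three parameter totals below follow exactly, and no other
padding/rounding convention reproduces all three.

| | conv filters | kernels | dropout | dense head | flatten | parameters |
| --- | --- | --- | --- | --- | --- | --- |
| Model-1 | 400, 256, 178, 88, 44 | 20, 15, 7, 5, 3 | .5 .5 .5 .25 .25 | 1 | 63×44 = 2772 | 1,956,651 |
| Model-2 | 600, 400, 256, 178, 88 | 20, 15, 10, 7, 20 | .25 ×5 | 1 | 53×88 = 4664 | 5,274,443 |
| Model-3 | 256, 128, 72, 36 | 5 ×4 | .5 ×4 | 50, 32, 1 | 131×36 = 4716 | 462,167 |

Model-2's third convolution is 256 filters: enumerating candidate
widths shows 256 is the only width consistent with the architecture's
stated 5,274,443-parameter total (266 would give 5,326,913).

Parameter counting is analytic — `(K·D + 1)·L` per convolution,
`(fan_in + 1)·units` per dense layer, nothing for pool/dropout/flatten
— and is enforced against the instantiated backend at build time: a
mismatch raises immediately, because it can only mean the architecture
was transcribed wrongly. Per-convolution multiply counts are
`K·(N−K+1)·D·L`, i.e. Θ(K·N·D·L) per example; `conv_cost_profile`
exposes the audit and a test compares it with multiplies measured from
the backend's actual matmul operand shapes.

## Training backend

No tensor-computation framework is used: the networks are trained by a
NumPy backend that expresses convolution as im2col + BLAS matrix
products, with explicit backpropagation. Design points:

- float32 arithmetic throughout; the col2im gradient is computed as one
  GEMM per kernel tap to keep memory access contiguous.
- Inverted dropout with a dedicated fast bit generator (SFC64) per
  dropout layer, seeded from the model seed.
- Optimizer: Adam (lr 1e-3, β 0.9/0.999), binary cross-entropy on the
  sigmoid output, gradient taken at the logit. Loss and optimizer are
  conventional defaults for a sigmoid head and are config-exposed;
  no class weighting is applied by default.
- Default schedule: 6 epochs, batch 32.
- All randomness (init, shuffling, dropout) flows from integer seeds,
  so identical runs are bit-identical on a fixed BLAS build; per-epoch
  history reports running mean batch loss/accuracy.

He initialization is used for ReLU layers and Glorot for the sigmoid
head. Ties in max-pooling resolve to the earlier sample.

## Evaluation

Confusion counts use abnormal = positive class. Accuracy, sensitivity
(= recall), specificity and precision are the standard confusion-count
ratios; 0/0 ratios surface as NaN sentinels rather than silent zeros,
since a silent zero would corrupt model comparisons under class
imbalance. F1 is the harmonic mean of precision and recall. The ROC
curve sweeps score thresholds (scikit-learn's sweep) and AUC is the
trapezoidal area, which the tests verify equals pairwise concordance
probability with ties counted one half. Reported loss is mean binary
cross-entropy.

## Pipeline

`run_pipeline` chains simulate → add noise → denoise → segment →
split → train → evaluate from a single config and writes
`manifest.json`, `metrics.json`, `history.json`, `roc.csv`,
`confusion.csv`. The default pipeline filter is the median filter. Stage
seeds derive deterministically from the run seed and are recorded in
the manifest; artifacts contain no timestamps, so identical configs
produce byte-identical outputs. Stage failures raise a stage-named
error and map to distinct CLI exit codes.

## Test problem sizes

The heavier checks run at sizes chosen to keep the full suite fast on a
single CPU while remaining informative: the learning check trains
Model-3 (6 epochs, batch 32) on 2000 beats generated at 20 dB SNR with
half abnormal beats, asserting ≥0.95 training accuracy and ≥0.95
held-out AUC, with a shuffled-label control that must stay within 0.10
of the majority-class fraction on the held-out split; the filter
benchmark property uses 20 records of 30 s at 10 dB SNR; the
reproducibility check runs the pipeline twice on a 120 s record with
2 training epochs.

## Known limitations

- The synthetic generator's simplifications (above) mean classifier
  metrics here say nothing quantitative about clinical data.
- The NumPy backend is single-threaded and CPU-bound; it is built for
  correctness, reproducibility and exact parameter accounting, not for
  large-scale training.
- Binary labels collapse the rich beat-symbol alphabet; no per-class
  arrhythmia taxonomy is attempted.
- Windowed-filter edge handling and the wavelet extension mode are
  reflection-based conventions; other conventions change a half-window
  at each edge.
- `psnr` requires an explicit `levels` argument for references with
  zero dynamic range.
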