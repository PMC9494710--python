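# Methods

This note documents the models and procedures semglite implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Surface electromyography (sEMG) records the electrical activity of
contracting muscle from skin electrodes. The package targets a 16-gesture
recognition task over 6 forearm channels sampled at 2 kHz, with the model
destined for a microcontroller whose flash is 2 MB — so classifier size is
a first-class design constraint alongside accuracy.

## Preprocessing

Raw channels pass through, in order:

1. third-order Butterworth high-pass at 20 Hz (motion-artifact removal);
2. optional Butterworth low-pass — disabled by default. The acquisition
   chain's low-pass sits at 2 kHz, i.e. at the sampling rate and above the
   digital Nyquist limit (1 kHz), so it is treated as an analog
   anti-aliasing stage with no digital counterpart. Configuring a digital
   cutoff at or above Nyquist raises a configuration error.
3. second-order IIR notch at 50 Hz with Q = 30 (power-line hum; no
   bandwidth was dictated by the acquisition setup, Q = 30 gives a ~1.7 Hz
   −3 dB width, narrow enough to leave the 30–70 Hz neighbourhood intact);
4. per-channel min-max scaling onto [0, 1], computed over the whole
   recording portion being processed. A constant channel maps to 0.5 with
   a warning.

All filtering is zero-phase (`sosfiltfilt`), appropriate offline and free
of inter-channel group-delay skew; magnitude attenuations quoted in tests
are therefore those of the squared frequency response. Scaling statistics
are computed *after* the train/test cut (see Splits), never across it.

## Windowing and features

Network inputs are 200-sample windows (100 ms) per channel, stacked into
`200 × 6 × 1` tensors. Successive windows are non-overlapping (step 200),
consistent with the non-overlapping 100-sample frames used inside each
window. Indices are 0-based and windows half-open.

Scalar time-domain features — MAV, WL, SSC, ZC, RMS — are computed on
100-sample sub-windows slid one sample at a time across the window,
giving a 101-point stream zero-padded to 200 so every representation has
the same tensor shape. MAV is the mean absolute amplitude (its occasional
conflation with RMS in the literature notwithstanding); SSC and ZC use an
amplitude threshold ε (default 0.01 of the normalized range) to reject
noise-level wiggles. One step at 2 kHz is 0.5 ms; steps here are always
expressed in samples.

Time-frequency features split each window per channel into two 100-sample
frames and replace each frame by its 100 two-sided DFT magnitudes (kept
two-sided so tensor dimensions are unchanged). The fused FFT+RMS variant
rescales every spectral frame to unit RMS and multiplies by the raw
frame's time-domain RMS, so the representation carries spectral shape and
contraction intensity simultaneously; by construction the output frame's
RMS equals the raw frame's RMS. This fusion is one concrete reading of an
under-specified construction and is isolated in a single function so
alternatives can be swapped. The DFT is validated against a naive O(N²)
oracle at 1e−9 relative tolerance.

## Architectures

Four variants over the 200 × 6 × 1 input, 16-way softmax output:

| variant | stack |
|---|---|
| CNN | conv 40×6 (1→128) → flatten → dropout 0.2 → dense 16 |
| CNN+LSTM | conv 40×6 (1→128) → 200×128 sequence → LSTM 32 → dropout → dense 16 |
| 2D CNN+LSTM | conv 40×6 (1→128, same) → conv 20×6 (128→8, valid) → 181×8 sequence → LSTM 32 → dropout → dense 16 |
| 2D CNN+2D LSTM | as above with LSTM 32 → LSTM 16 |

A leaky ReLU (slope 0.01) precedes the softmax. Geometry: in the
two-convolution variants the first convolution is same-padded in both
axes (200×6 preserved) so the second, valid 20×6 kernel can span the
channel axis and produce the 181×8 map (200−20+1 = 181, 6−6+1 = 1) that
is reshaped into the LSTM's input sequence. The single-convolution
variants have no second width-6 kernel to feed, so their convolution
collapses the channel axis immediately (same along time, valid across
channels). Max-pooling layers exist in the declarative spec but default
to size 1 (identity), since the size accounting below leaves no room for
a pooling reduction; a config switch enables real pooling.

## Size accounting

Two parameter counts coexist deliberately:

* **Budget convention** (`size_estimate`): conv layers count
  `kernel_h · kernel_w · n_out · n_in`, a reshape counts the product of
  its output dimensions, an LSTM counts flattened-input-length × hidden
  units, and everything else counts zero; a literal list of training
  variables (128, 20, 32) is added and kilobytes are `total · 4 / 1024`.
  On the default 2D CNN+LSTM this yields 30720 + 122880 + 1448 + 46336 +
  180 = 201564 ≈ 787.36 kB. The convention ignores biases and the 4×
  gate structure of LSTM weights; it is reproduced exactly because it is
  the yardstick used for the flash budget this project targets.
* **True count** (`count_trainable_params`): conv `(kh·kw·c_in + 1)·c_out`,
  dense `(in + 1)·out`, LSTM `4·((in + hidden + 1)·hidden)`. This matches
  the training engine's parameter arrays exactly (asserted at network
  build time) and is what the serialized artifact size follows: the
  default model is ~159.5 k float32 parameters ≈ 0.64 MB, comfortably
  under the 2 MB flash limit.

## Training engine

No deep-learning framework is part of the dependency set; the classifiers
are trained by a compact numpy engine (`semglite.nn`) implementing exactly
the required layers with reverse-mode gradients in float32. Convolution
uses im2col GEMMs where the column matrix is affordable, and a
full-correlation GEMM formulation for the wide second convolution whose
kernel spans the channel axis (both paths are finite-difference checked in
the test suite). The LSTM uses the standard i/f/g/o gating with
forget-gate bias initialized to 1; weights are Glorot-uniform. Softmax and
cross-entropy are fused for numerical stability.

Optimization defaults: joint end-to-end training of the conv and LSTM
blocks with Adam, initial learning rate 0.01 cut to 20% of its value
every 20 epochs (a reduction *by* 80%), batch size 32 (128 for the
pure-CNN variant), dropout 0.2, cross-entropy loss, early stop once train
loss ≤ 0.01 and validation loss ≤ 0.1. An optional two-phase mode (SGDM
warm-up, then Adam) mirrors the alternative two-step tuning strategy.
Validation runs once per epoch by default; a config field raises it to
twice. Given a seed, training is bit-reproducible.

## Splits and evaluation

*Intra-experiment*: each trial is cut into contiguous thirds — first two
thirds train, last third test — **on the raw signal, before
preprocessing**, so min-max statistics cannot leak across the cut. A 10%
contiguous tail of the training block is held out for validation (the
protocol leaves the validation fraction open; a temporal tail respects
ordering). *Inter-experiment*: one full repetition of the 16-gesture
protocol trains, another tests. A leakage guard asserts on every dataset
and every evaluation that no window sits in two splits.

Evaluation reports a 16×16 confusion matrix (counts; row-normalized
percentages available for display), per-class accuracies — undefined (NaN),
never zero, for classes absent from the test split — and overall accuracy
= trace/total. `compare_grid` trains every feature × architecture
combination and tabulates accuracy against both size measures.

## Synthetic data

Real subject recordings for this protocol are not publicly deposited, so
the package ships a seeded generator used by all system tests. To first
order sEMG is band-limited Gaussian noise amplitude-modulated by muscle
activation, and that is what is generated: each of 16 classes has a
distinct per-channel activation weight vector (pairwise L1 distance
> 0.2 enforced) and a carrier band inside the physiological 20–450 Hz
range; trials are 3 s contractions with raised-cosine 200 ms on/off ramps,
1 s rest gaps, 3 repetitions per class, and a white noise floor at 5% of
the unit carrier RMS (a realistic rest-to-contraction amplitude ratio).
Classes 7 and 8 share a carrier band and have nearly identical activation
patterns (L1 distance 0.25) to mimic gesture pairs driven by shared
musculature, which dominate real confusion matrices.

The generator does **not** model motor-unit action potentials, electrode
crosstalk, fatigue drift, or inter-subject variability. Passing the
end-to-end benchmark therefore shows that the pipeline, features,
networks and training loop function correctly and that spectrally
distinct activation patterns are recoverable — it does not certify
accuracy on human data.

## Benchmark scale

The end-to-end check trains the default 2D CNN+LSTM on FFT+RMS features
of the default synthetic protocol (16 classes × 3 repetitions × 3 s →
1440 windows, 864/96/480 train/val/test under the intra split) for up to
30 epochs — problem sizes chosen so the whole suite runs comfortably on a
single CPU — and requires ≥ 0.90 test accuracy. For this reduced-epoch
run the learning-rate decay interval is compressed proportionally (every
5 epochs instead of every 20), keeping the initial rate and decay factor:
the 20-epoch interval is calibrated to the full 200-epoch training and
leaves a 30-epoch run both under-decayed and under-converged.
Training-time quantities (loss curves, accuracies) are computed at run
time, never stored.

## Known limitations

* The engine is CPU/numpy only; it is deliberately minimal (no strided
  convolution, no bidirectional LSTM) and sized for these architectures.
* The FFT+RMS fusion and the validation fraction are project choices
  where the underlying recipe is open; both are parameterized.
* `size_estimate`'s training-variables list (128, 20, 32) is carried as
  an opaque constant of the budget convention; its provenance (batch
  size, map count, hidden units) is not modelled.
* Bit-reproducibility holds for a fixed BLAS; across different BLAS
  builds results may differ in the last float32 ulps.
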