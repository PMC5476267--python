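# Methods

## Problem and pipeline

`birdnmf` classifies bird species from their vocalizations. A recording is
reduced to its syllables — short spectral pulses of tens to hundreds of
milliseconds — and every syllable is summarized by statistics of frame-level
acoustic features; a support-vector machine labels syllables, and a majority
vote over syllables labels the recording. The package's core contribution is
the pair of frame-level front-ends built on non-negative matrix
factorization (NMF) of magnitude spectrograms, used alongside the
conventional MFCC baseline.

The stages, in pipeline order:

1. **Pre-processing.** Audio is converted to mono at 22 050 Hz and filtered
   with a zero-phase Butterworth band-pass (order 4, 1–10.5 kHz), the band
   where bird vocal energy concentrates; this suppresses low-frequency
   ambient noise and out-of-band interference.
2. **Spectrogram.** Hamming-windowed STFT, 20 ms window, 10 ms shift
   (441 / 220 samples at 22 050 Hz), 512-point FFT → F = 257 magnitude bins.
   Frames are taken without padding: `T = floor((len − win) / hop) + 1`.
3. **Syllable segmentation.** Syllables are modeled as pulses that rise
   above a threshold in the per-frame peak-magnitude trace (dB relative to
   the global spectrogram maximum). Iterative peak-stripping: take the
   loudest unconsumed frame, grow the segment while the trace stays within
   20 dB of that peak, consume it, repeat until the loudest remaining frame
   is more than 20 dB below the global maximum. Segments shorter than
   3 frames are discarded (30 ms of analysis support is the minimum for
   stable per-syllable statistics).
4. **Frame-level features** (below).
5. **Temporal integration.** Per syllable, each feature column is collapsed
   to its mean, population (1/N) standard deviation and moment skewness
   (g1 = m3 / m2^{3/2}, defined as 0 for constant sequences), concatenated
   statistic-major (all means, all stds, all skews): 3·D values per
   syllable.
6. **Classification.** Features are z-scored with training statistics and
   fed to a one-vs-one RBF-kernel SVM. (C, γ) are selected by 5-fold inner
   cross-validation over a log₂ grid (C ∈ 2^{−3..7}, γ ∈ 2^{−7..3}, steps
   of 2), ties resolved toward smaller C then smaller γ. Recordings are
   labeled by majority vote over their syllables, ties toward the earliest
   class in sorted order.

## NMF under the generalized Kullback–Leibler divergence

Given a non-negative matrix V (F × T), NMF finds W (F × K) and H (K × T),
all entries ≥ 0, minimizing

    D(V ‖ WH) = Σᵢⱼ [ Vᵢⱼ log(Vᵢⱼ / (WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ]

by the classical multiplicative updates

    W ← W ⊗ ((V ⊘ WH) Hᵀ) ⊘ (1 Hᵀ),
    H ← H ⊗ (Wᵀ (V ⊘ WH)) ⊘ (Wᵀ 1),

which never increase the divergence and preserve non-negativity.
Initialization follows a multi-restart protocol: 10 random non-negative
(W, H) pairs (entries uniform (0, 1], scaled by mean(V) so the initial
product is on the data's scale), keep the pair with the smallest Frobenius
distance ‖V − WH‖, then refine with at most 200 KL update iterations.

### The two NMF front-ends

**NMF_CC (learned filter bank, unsupervised).** All training spectrograms
are concatenated column-wise into one matrix (F × n_s) and decomposed at
rank K = 40. The basis columns, transposed, become a 40-filter auditory
filter bank; filter-bank log energies are decorrelated with an orthonormal
DCT-II, coefficients C1…C12 are kept (C0, a pure gain term, is discarded)
and the frame log-energy is appended → 13 dimensions, 26 with deltas. The
MFCC baseline is the identical pipeline with 40 triangular mel filters.

**H_CC + G_NMF (per-class bases, supervised).** For each species, the
class's training spectrograms are pooled and decomposed at rank K = 4; the
per-class bases are concatenated into W_bs (F × K·C) and frozen. At feature
time, activations H_bs are inferred for a spectrogram by running only the H
update against the fixed W_bs; features are the DCT of log activations
(H_Log), coefficients C1…C13, plus the maximum-gain index
G_NMF(t) = argmax_k H_bs[k, t] (1-based, so the index can be read against
the class blocks of W_bs). With C = 12 species and K = 4 there are 48 H_Log
values per frame; the feature vector is 14-dimensional. Combined front-ends
concatenate the cepstral features before the activation features; deltas,
when used, are applied to the combined vector (27 → 54 dimensions).

G_NMF is written as an index rather than the maximum value itself: the
identity of the most active basis vector carries the class information (the
"maximum gain" name notwithstanding), and the index reading keeps the
feature bounded in [1, K·C]. The max-value reading can be obtained from the
activations if needed.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| band edges | 1–10.5 kHz | bird vocal energy band; Butterworth order 4, zero-phase |
| window / shift | 20 / 10 ms | standard short-time analysis resolution |
| n_fft | 512 | next power of two above the 441-sample window |
| segmentation threshold | 20 dB | drop from peak that ends a syllable |
| min syllable length | 3 frames | shorter segments give unstable statistics |
| K (filter bank) | 40 | matches the mel-bank size it replaces |
| K per class (SBVs) | 4 | compact per-species spectral signature |
| NMF restarts / max iterations | 10 / 200 | multi-restart initialization protocol |
| NMF early-stop tolerance | 1e-6 relative KL change | the iteration cap alone leaves convergence undefined; this stops refinement when the divergence has plateaued |
| inner / outer CV folds | 5 / 6 | hyperparameter search / evaluation protocol |

## Numerical choices

- **Epsilon floors.** 1e-12 inside every NMF division (0/0 guards) and
  1e-10 before every log (silent frames must produce finite
  large-negative values, never NaN). These do not materially move the KL
  fixed points.
- **DCT.** Type-II, orthonormal, so the transform is an isometry and the
  discarded C0 carries exactly the mean (gain) of the log energies.
- **Precision.** The core factorization runs in double precision. The
  pooled corpus-scale fits (filter-bank learning, per-class bases,
  batched activation inference) run in single precision — the matrices span
  entire training folds and the elementwise updates are memory-bound; basis
  vectors are cast back to double for feature extraction. The divergence
  trace is always reported in double precision.
- **Restart selection** uses the Euclidean (Frobenius) distance even though
  refinement minimizes KL, per the initialization protocol.
- **Normalization of learned filters.** NMF leaves a per-component scale
  ambiguity; learned filters are L1-normalized and sorted by peak-frequency
  bin so banks are comparable across folds. Per-class SBVs are left
  unnormalized (the scale is absorbed by the inferred activations).
- **Deltas** are least-squares regression slopes over ±2 frames with edge
  replication, and never straddle recording boundaries.
- **Degenerate inputs.** An all-zero activation column maps to G_NMF = 1 by
  first-index tie-break; a recording in which segmentation finds no
  syllable is unclassifiable and counted as an error by the evaluation
  harness; empty segment lists are valid segmentation output.
- **Batched activation inference.** The KL activation update decouples
  across spectrogram columns, so the harness infers activations for all
  recordings of a split in one call and splits the frames afterwards;
  per-recording inference gives the same fixed points.

## Synthetic data: what it emulates, and what it does not

Real labeled corpora of the target scale are impractical to ship, so all
tests and the acceptance experiment run on a generator with known ground
truth. Each species is defined by a pair of center frequencies inside the
bird band (primary centers pairwise ≥ 500 Hz apart), a syllable duration
range, a syllable rate and a chirp-slope range. A recording is a train of
syllables — sums of linear chirps at the species frequencies under a
raised-cosine envelope — at exponentially distributed gaps, plus white
noise at a band-limited SNR (default 20 dB, a mildly noisy field
recording). This reproduces the structure the method relies on: repeated
threshold-exceeding pulses with a distinctive low-rank spectral signature
per species.

It does **not** reproduce reverberation, ambient soundscapes, overlapping
singers, recording-chain variation, or the within-species repertoire
diversity of real birds. Passing tests therefore demonstrate that the
implementation is correct and that the front-ends separate species whose
spectra differ — not that field-recording accuracy would match the
synthetic numbers, which are near-ceiling by construction. A
`separation_scale` knob shrinks all between-species differences toward zero
to verify that task difficulty, not harness artifacts, drives accuracy.

Default fixture: 4 species × 30 recordings × 2 s. At the standard frame
rate this pools ≈ 20 000 training frames per fold — the scale of a
realistic corpus-level factorization — while a full 6-fold experiment for
both NMF front-ends completes in minutes on one core.

## Known limitations

- The segmenter is the simple peak-stripping reading of the
  pulse-threshold model; it is not noise-robust and makes no attempt at
  call/song discrimination. No gold boundaries exist to tune it against.
- Whether the 20 dB threshold should be referenced to the global spectrogram
  peak or a per-recording noise floor is ambiguous; the global-peak reading
  is implemented.
- KL-NMF converges to local optima; the multi-restart protocol mitigates
  but does not remove seed dependence.
- Outer folds are stratified by species (the balanced-groups reading);
  fully random fold composition is not reproduced.
- mp3 decoding is out of scope; inputs are WAV.
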