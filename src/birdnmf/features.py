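"""Short-time feature extraction front-ends.

Three per-frame feature families are implemented:

* **MFCC** — the baseline: triangular mel filter bank, log energies,
  orthonormal DCT-II, coefficients C1..C12 plus frame log-energy (13 dims;
  26 with deltas).
* **NMF_CC** — identical pipeline, but the mel bank is replaced by a filter
  bank learned without supervision by KL-NMF on training spectrograms: the
  basis columns of W, transposed into filters, L1-normalized and ordered by
  peak frequency.
* **H_CC (+ G_NMF)** — supervised: a per-species spectral basis (K columns
  per class) is learned by KL-NMF, all bases are concatenated into W_bs, and
  test-frame activations H_bs are inferred against the fixed W_bs. Features
  are the DCT of log activations (H_Log), C1..C13, optionally appending the
  per-frame maximum-gain index G_NMF = argmax_k H_bs[k, t] (1-based), giving
  14 dims.

Deltas are least-squares regression slopes over +/-2 frames with edge
replication; combined front-ends concatenate feature columns frame-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.fft

from . import nmf_core
from .preprocess import Spectrogram

LOG_FLOOR = 1e-10
DEFAULT_N_FILTERS = 40
DEFAULT_K_PER_CLASS = 4
DEFAULT_N_CEPS = 12
DEFAULT_N_CEPS_HCC = 13
DEFAULT_DELTA_WINDOW = 2


@dataclass
class FilterBank:
    """A bank of spectral filters (rows) over FFT bins (columns)."""

    filters: np.ndarray  # (K, F), non-negative
    kind: str  # "mel" or "nmf"
    freqs: np.ndarray  # (F,) Hz per bin

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=np.float64)
        if np.any(self.filters < 0):
            raise ValueError("filters must be non-negative")
        if np.any(self.filters.sum(axis=1) <= 0):
            raise ValueError("every filter needs at least one positive entry")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


@dataclass
class SbvModel:
    """Concatenated per-class spectral basis vectors W_bs (F x K*C)."""

    W_bs: np.ndarray
    class_labels: list[str]
    K_per_class: int

    def __post_init__(self) -> None:
        expected = self.K_per_class * len(self.class_labels)
        if self.W_bs.shape[1] != expected:
            raise ValueError(
                f"W_bs has {self.W_bs.shape[1]} columns, expected "
                f"K*C = {expected}"
            )

    def class_block(self, label: str) -> slice:
        """Column slice of W_bs holding the basis of ``label``."""
        i = self.class_labels.index(label)
        return slice(i * self.K_per_class, (i + 1) * self.K_per_class)

    def class_of_column(self, k: int) -> str:
        """Class owning 0-based basis column ``k``."""
        return self.class_labels[k // self.K_per_class]


@dataclass
class ShortTimeFeatures:
    """Per-frame feature matrix X (frames x D) with a named column layout."""

    X: np.ndarray
    layout: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.layout):
            raise ValueError("X width must equal layout length")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.layout)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int = DEFAULT_N_FILTERS,
    n_fft: int = 512,
    sample_rate: int = 22050,
) -> FilterBank:
    """Triangular filters equally spaced on the mel scale from 0 to Nyquist."""
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    nyquist = sample_rate / 2.0
    freqs = scipy.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    edges_hz = _mel_to_hz(np.linspace(0.0, _hz_to_mel(nyquist), n_filters + 2))
    filters = np.zeros((n_filters, len(freqs)))
    for k in range(n_filters):
        lo, mid, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        rising = (freqs - lo) / max(mid - lo, 1e-12)
        falling = (hi - freqs) / max(hi - mid, 1e-12)
        filters[k] = np.clip(np.minimum(rising, falling), 0.0, None)
    if np.any(filters.sum(axis=1) <= 0):
        raise ValueError(
            f"{n_filters} filters exceed the frequency resolution of "
            f"n_fft={n_fft}: some filter spans no FFT bin"
        )
    return FilterBank(filters, kind="mel", freqs=freqs)


def _concat_spectrograms(specs: Sequence[Spectrogram]) -> np.ndarray:
    if not specs:
        raise ValueError("need at least one spectrogram")
    F = specs[0].n_bins
    if any(s.n_bins != F for s in specs):
        raise ValueError("all spectrograms must share the same bin count")
    return np.concatenate([s.V for s in specs], axis=1)


def learn_nmf_filterbank(
    training_specs: Sequence[Spectrogram],
    K: int = DEFAULT_N_FILTERS,
    n_restarts: int = nmf_core.DEFAULT_N_RESTARTS,
    max_iter: int = nmf_core.DEFAULT_MAX_ITER,
    tol: float = nmf_core.DEFAULT_TOL,
    seed: int | None = None,
    dtype: np.dtype | type = np.float32,
) -> FilterBank:
    """Learn an auditory filter bank by KL-NMF of pooled training spectra.

    All training spectrogram columns are concatenated into one matrix
    V (F x n_s) and decomposed at rank ``K``; the basis columns become the
    filters. Each filter is L1-normalized (removing the NMF scale ambiguity)
    and filters are sorted by peak-frequency bin so the bank is comparable
    across training folds. The pooled factorization runs in single
    precision by default — the matrix spans an entire training corpus.
    """
    V = _concat_spectrograms(training_specs)
    model = nmf_core.nmf_decompose(
        V, K, n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed,
        dtype=dtype,
    )
    filters = model.W.T.astype(np.float64)
    norms = np.maximum(filters.sum(axis=1, keepdims=True), nmf_core.EPS)
    filters /= norms
    order = np.argsort(filters.argmax(axis=1), kind="stable")
    return FilterBank(filters[order], kind="nmf", freqs=training_specs[0].freqs)


def cepstral_features(
    spec: Spectrogram,
    bank: FilterBank,
    n_ceps: int = DEFAULT_N_CEPS,
) -> ShortTimeFeatures:
    """Cepstral coefficients through an arbitrary filter bank (MFCC / NMF_CC).

    Per frame: filter-bank outputs, floored log, orthonormal DCT-II; C0 is
    discarded and C1..C_n_ceps kept; the frame log-energy (log of summed
    squared magnitude, floored) is appended. D = n_ceps + 1.
    """
    if bank.filters.shape[1] != spec.n_bins:
        raise ValueError("filter bank bin count must match spectrogram")
    if n_ceps >= bank.n_filters:
        raise ValueError("n_ceps must be < number of filters")
    E = bank.filters @ spec.V  # (K, T)
    logE = np.log(np.maximum(E, LOG_FLOOR))
    ceps = scipy.fft.dct(logE, type=2, norm="ortho", axis=0)
    frame_log_energy = np.log(np.maximum((spec.V**2).sum(axis=0), LOG_FLOOR))
    X = np.vstack([ceps[1 : n_ceps + 1], frame_log_energy[None, :]]).T
    prefix = "c" if bank.kind == "mel" else "ncc"
    layout = [f"{prefix}{i}" for i in range(1, n_ceps + 1)] + ["logE"]
    return ShortTimeFeatures(X, layout)


def learn_class_sbvs(
    per_class_specs: Mapping[str, Sequence[Spectrogram]],
    K: int = DEFAULT_K_PER_CLASS,
    n_restarts: int = nmf_core.DEFAULT_N_RESTARTS,
    max_iter: int = nmf_core.DEFAULT_MAX_ITER,
    tol: float = nmf_core.DEFAULT_TOL,
    seed: int | None = None,
    dtype: np.dtype | type = np.float32,
) -> SbvModel:
    """Learn per-class spectral basis vectors and concatenate them.

    For each class the training spectrograms are concatenated and decomposed
    at rank ``K``; the per-class bases W_i are column-concatenated into W_bs
    (F x K*C) in class order. Per-class NMF seeds are derived
    deterministically from ``seed``; the pooled per-class factorizations run
    in single precision by default.
    """
    labels = list(per_class_specs.keys())
    if not labels:
        raise ValueError("need at least one class")
    blocks = []
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(labels))]
    for label, sub_seed in zip(labels, child_seeds):
        specs = list(per_class_specs[label])
        if not specs or sum(s.n_frames for s in specs) == 0:
            raise ValueError(f"class {label!r} has no training frames")
        V = _concat_spectrograms(specs)
        model = nmf_core.nmf_decompose(
            V, K, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=sub_seed, dtype=dtype,
        )
        blocks.append(model.W)
    return SbvModel(np.concatenate(blocks, axis=1), labels, K)


def hcc_from_activations(
    H_bs: np.ndarray,
    n_ceps: int = DEFAULT_N_CEPS_HCC,
    with_gnmf: bool = True,
) -> ShortTimeFeatures:
    """H_CC features from an already-inferred activation matrix (K*C x T)."""
    H_bs = np.asarray(H_bs, dtype=np.float64)
    if n_ceps >= H_bs.shape[0]:
        raise ValueError("n_ceps must be < number of basis vectors K*C")
    H_log = np.log(np.maximum(H_bs, LOG_FLOOR))
    ceps = scipy.fft.dct(H_log, type=2, norm="ortho", axis=0)
    cols = [ceps[1 : n_ceps + 1]]
    layout = [f"hcc{i}" for i in range(1, n_ceps + 1)]
    if with_gnmf:
        # argmax returns the first index on ties, so an all-zero column maps
        # to basis vector 1 by convention
        gnmf = np.argmax(H_bs, axis=0) + 1.0
        cols.append(gnmf[None, :])
        layout.append("gnmf")
    return ShortTimeFeatures(np.vstack(cols).T, layout)


def hcc_features(
    spec: Spectrogram,
    model: SbvModel,
    n_ceps: int = DEFAULT_N_CEPS_HCC,
    with_gnmf: bool = True,
    max_iter: int = nmf_core.DEFAULT_MAX_ITER,
    tol: float = nmf_core.DEFAULT_TOL,
    seed: int | None = None,
) -> ShortTimeFeatures:
    """Activation-derived features against fixed class bases.

    Activations H_bs are inferred for the spectrogram against the frozen
    W_bs; features are the DCT of log activations (C1..C_n_ceps) plus,
    when ``with_gnmf``, the 1-based index of the most active basis vector.
    """
    if model.W_bs.shape[0] != spec.n_bins:
        raise ValueError("SBV model bin count must match spectrogram")
    H_bs = nmf_core.infer_activations(
        spec.V, model.W_bs, max_iter=max_iter, tol=tol, seed=seed,
        dtype=model.W_bs.dtype,
    )
    return hcc_from_activations(H_bs, n_ceps=n_ceps, with_gnmf=with_gnmf)


def append_deltas(
    feats: ShortTimeFeatures, window: int = DEFAULT_DELTA_WINDOW
) -> ShortTimeFeatures:
    """Append first-derivative (delta) features, doubling D.

    Deltas are the least-squares regression slope over +/-``window`` frames,
    d[t] = sum_n n (x[t+n] - x[t-n]) / (2 sum_n n^2), with edge replication.
    """
    X = feats.X
    T = X.shape[0]
    pad = np.concatenate(
        [np.repeat(X[:1], window, axis=0), X, np.repeat(X[-1:], window, axis=0)],
        axis=0,
    )
    denom = 2.0 * sum(n * n for n in range(1, window + 1))
    deltas = np.zeros_like(X)
    for n in range(1, window + 1):
        deltas += n * (pad[window + n : window + n + T] - pad[window - n : window - n + T])
    deltas /= denom
    layout = feats.layout + [f"d_{name}" for name in feats.layout]
    return ShortTimeFeatures(np.hstack([X, deltas]), layout)


def concat_features(a: ShortTimeFeatures, b: ShortTimeFeatures) -> ShortTimeFeatures:
    """Frame-wise column concatenation; a's columns precede b's."""
    if a.n_frames != b.n_frames:
        raise ValueError(
            f"frame counts differ: {a.n_frames} vs {b.n_frames}"
        )
    return ShortTimeFeatures(np.hstack([a.X, b.X]), a.layout + b.layout)
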