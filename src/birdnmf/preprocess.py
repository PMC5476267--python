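"""Audio ingestion, band-pass filtering, spectrogram computation and syllable
segmentation.

Bird vocalizations are treated as sequences of syllables: short (tens to
hundreds of ms) spectral pulses separated by quieter gaps. The pipeline here
is the classical front half of a bioacoustic classifier: read mono audio,
band-pass to the 1-10.5 kHz region where most bird energy lives, compute a
Hamming-windowed magnitude STFT (20 ms window / 10 ms shift), and detect
syllables as regions of the per-frame peak-magnitude trace that stay within a
fixed dB drop (default 20 dB) of a local peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft
import scipy.io.wavfile
import scipy.signal

# Standard analysis configuration (shared defaults across the package).
DEFAULT_SAMPLE_RATE = 22050
DEFAULT_WINDOW_S = 0.020
DEFAULT_SHIFT_S = 0.010
DEFAULT_N_FFT = 512
DEFAULT_BAND_LOW_HZ = 1000.0
DEFAULT_BAND_HIGH_HZ = 10500.0
DEFAULT_BUTTER_ORDER = 4
DEFAULT_THRESHOLD_DB = 20.0
DEFAULT_MIN_FRAMES = 3

_DB_FLOOR = 1e-12


class DegenerateInputError(ValueError):
    """Raised for inputs too short or empty to analyze."""


@dataclass
class AudioSignal:
    """A mono audio signal.

    Attributes
    ----------
    samples : np.ndarray
        1-D float array of amplitudes.
    sample_rate : int
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Spectrogram:
    """Non-negative magnitude spectrogram, frequency bins x frames."""

    V: np.ndarray
    freqs: np.ndarray
    frame_shift: float
    window_length: float
    sample_rate: int

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.V.ndim != 2:
            raise ValueError("V must be 2-D (bins x frames)")
        if self.V.shape[0] != len(self.freqs):
            raise ValueError("freqs length must match number of bins")
        if np.any(self.V < 0):
            raise ValueError("magnitude spectrogram must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.V.shape[0]

    @property
    def n_frames(self) -> int:
        return self.V.shape[1]


@dataclass(frozen=True)
class SyllableSegment:
    """Half-open frame interval [start_frame, end_frame) holding one syllable.

    ``peak_db`` is the segment's peak level in dB relative to the global
    spectrogram maximum (hence <= 0).
    """

    start_frame: int
    end_frame: int
    peak_db: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError("require 0 <= start_frame < end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def read_audio(path: str | Path, target_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Read a WAV file as a mono signal at ``target_rate``.

    Multi-channel audio is averaged across channels; integer PCM is scaled to
    [-1, 1]; resampling uses a polyphase filter.
    """
    path = Path(path)
    try:
        rate, data = scipy.io.wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises assorted ValueError subtypes
        raise OSError(f"could not read audio file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise DegenerateInputError(f"audio file {path} contains no samples")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    sig = AudioSignal(data, int(rate))
    return resample(sig, target_rate)


def write_audio(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV."""
    peak = np.max(np.abs(signal.samples)) or 1.0
    scaled = np.clip(signal.samples / max(peak, 1.0), -1.0, 1.0)
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    scipy.io.wavfile.write(Path(path), signal.sample_rate, pcm)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resampling to ``target_rate`` (identity if rates match)."""
    if signal.sample_rate == target_rate:
        return signal
    frac = Fraction(target_rate, signal.sample_rate)
    out = scipy.signal.resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, target_rate)


def bandpass(
    signal: AudioSignal,
    low: float = DEFAULT_BAND_LOW_HZ,
    high: float = DEFAULT_BAND_HIGH_HZ,
    order: int = DEFAULT_BUTTER_ORDER,
) -> AudioSignal:
    """Zero-phase Butterworth band-pass filter.

    The filter is applied forward-backward (``sosfiltfilt``) so syllable
    timing is preserved. Pass-band edges default to the 1-10.5 kHz region
    where bird vocal energy concentrates.
    """
    nyquist = signal.sample_rate / 2.0
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"upper band edge {high} Hz must be below Nyquist {nyquist} Hz"
        )
    sos = scipy.signal.butter(
        order, [low, high], btype="bandpass", fs=signal.sample_rate, output="sos"
    )
    out = scipy.signal.sosfiltfilt(sos, signal.samples)
    return AudioSignal(out, signal.sample_rate)


def magnitude_spectrogram(
    signal: AudioSignal,
    window: float = DEFAULT_WINDOW_S,
    shift: float = DEFAULT_SHIFT_S,
    n_fft: int = DEFAULT_N_FFT,
) -> Spectrogram:
    """Hamming-windowed magnitude STFT.

    Frames are taken without padding: T = floor((len - win) / hop) + 1 with
    win = floor(window * rate) and hop = floor(shift * rate) samples. Windows
    shorter than ``n_fft`` are zero-padded before the FFT, giving
    n_fft/2 + 1 frequency bins.
    """
    rate = signal.sample_rate
    win = int(window * rate)
    hop = int(shift * rate)
    if win < 1 or hop < 1:
        raise ValueError("window and shift must each cover at least one sample")
    if n_fft < win:
        raise ValueError(f"n_fft={n_fft} smaller than window of {win} samples")
    x = signal.samples
    if len(x) < win:
        raise DegenerateInputError(
            f"signal of {len(x)} samples is shorter than one {win}-sample window"
        )
    n_frames = (len(x) - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(win)[None, :]
    V = np.abs(scipy.fft.rfft(frames, n=n_fft, axis=1)).T
    freqs = scipy.fft.rfftfreq(n_fft, d=1.0 / rate)
    return Spectrogram(V, freqs, frame_shift=hop / rate,
                       window_length=win / rate, sample_rate=rate)


def segment_syllables(
    spec: Spectrogram,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> list[SyllableSegment]:
    """Detect syllables by iterative peak-stripping of the dB peak trace.

    The per-frame maximum magnitude (in dB relative to the global spectrogram
    maximum) serves as the syllable amplitude proxy. Repeatedly: take the
    loudest unconsumed frame; grow the segment left and right while the trace
    stays above (peak - threshold_db) and the frames are unconsumed; consume
    those frames; keep the segment if it spans at least ``min_frames``. Stops
    once the loudest remaining frame falls more than ``threshold_db`` below
    the global maximum. Returns sorted, disjoint segments; possibly empty.
    """
    if spec.n_frames < min_frames:
        return []
    trace = spec.V.max(axis=0)
    global_max = trace.max()
    if global_max <= 0:
        return []
    db = 20.0 * np.log10(np.maximum(trace, _DB_FLOOR * global_max) / global_max)
    consumed = np.zeros(spec.n_frames, dtype=bool)
    segments: list[SyllableSegment] = []
    masked = db.copy()
    while True:
        masked[consumed] = -np.inf
        peak_idx = int(np.argmax(masked))
        peak = masked[peak_idx]
        if peak < -threshold_db:
            break
        lo = peak_idx
        while lo > 0 and not consumed[lo - 1] and db[lo - 1] > peak - threshold_db:
            lo -= 1
        hi = peak_idx + 1
        while hi < len(db) and not consumed[hi] and db[hi] > peak - threshold_db:
            hi += 1
        consumed[lo:hi] = True
        if hi - lo >= min_frames:
            segments.append(SyllableSegment(lo, hi, float(peak)))
    segments.sort(key=lambda s: s.start_frame)
    return segments


def segments_to_frame(
    segments: list[SyllableSegment],
    recording_id: str,
    frame_shift: float = DEFAULT_SHIFT_S,
) -> pd.DataFrame:
    """Tabulate segments (one row per syllable) for CSV export."""
    rows = [
        {
            "recording_id": recording_id,
            "start_frame": s.start_frame,
            "end_frame": s.end_frame,
            "start_s": s.start_frame * frame_shift,
            "end_s": s.end_frame * frame_shift,
            "peak_db": s.peak_db,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["recording_id", "start_frame", "end_frame",
                 "start_s", "end_s", "peak_db"],
    )
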