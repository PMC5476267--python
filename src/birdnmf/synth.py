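"""Synthetic bird-vocalization generator with known ground truth.

Recordings are modeled the way the segmentation stage assumes real syllables
behave: each syllable is a short sinusoidal pulse — a sum of linear chirps at
a species' characteristic frequencies, shaped by a raised-cosine amplitude
envelope — separated by quieter gaps and overlaid with broadband white noise
at a controlled band-limited SNR. Each species is defined by a small set of
center frequencies inside the 1-10.5 kHz bird band, so its magnitude
spectrogram has a distinctive low-rank signature, which is exactly the
structure the NMF front-ends are designed to discover.

The module also provides planted rank-K factorizations (Gaussian-bump bases
with sparse activations) for verifying the NMF machinery against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    DEFAULT_SAMPLE_RATE,
    DEFAULT_SHIFT_S,
    AudioSignal,
    SyllableSegment,
    write_audio,
)

BAND_LOW_HZ = 1000.0
BAND_HIGH_HZ = 10500.0
MIN_SEPARATION_HZ = 500.0

# Default fixture scale: 4 species x 30 recordings x 2 s, sized so the
# pooled training matrix (~24k frames) matches a realistic corpus scale
DEFAULT_N_SPECIES = 4
DEFAULT_N_PER_SPECIES = 30
DEFAULT_DURATION_S = 2.0
DEFAULT_NOISE_DB = 20.0


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground-truth acoustic profile of one synthetic species."""

    name: str
    basis_freqs: tuple[float, ...]  # Hz, inside (1000, 10500)
    basis_widths: tuple[float, ...]  # Hz, envelope-induced bandwidth scale
    syllable_duration_range: tuple[float, float]  # seconds
    syllable_rate: float  # syllables / second
    chirp_slope_range: tuple[float, float]  # Hz / s

    def __post_init__(self) -> None:
        for f in self.basis_freqs:
            if not (BAND_LOW_HZ < f < BAND_HIGH_HZ):
                raise ValueError(f"basis frequency {f} Hz outside bird band")
        lo, hi = self.syllable_duration_range
        if lo > hi or lo <= 3 * DEFAULT_SHIFT_S:
            raise ValueError("syllable durations must exceed 3 frame shifts")


@dataclass
class SyntheticDataset:
    """Labeled recordings with true syllable boundaries."""

    recordings: list[tuple[AudioSignal, str, list[SyllableSegment]]]
    specs: list[SpeciesSpec]
    seed: int | None

    def __len__(self) -> int:
        return len(self.recordings)


def make_species_specs(
    n_species: int,
    seed: int | None = None,
    separation_scale: float = 1.0,
) -> list[SpeciesSpec]:
    """Deterministic species profiles with mutually separated spectra.

    Species primary frequencies are laid out on a grid across the bird band
    so every pair is separated by at least 500 Hz in its primary component
    (at ``separation_scale`` = 1). Shrinking ``separation_scale`` pulls all
    species toward the band center, making the classification task harder;
    it is a test knob, not a realism dial.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    usable_lo, usable_hi = BAND_LOW_HZ + 500.0, BAND_HIGH_HZ - 500.0
    step = (usable_hi - usable_lo) / (n_species - 1) if n_species > 1 else 0.0
    if separation_scale >= 1.0 and step < MIN_SEPARATION_HZ:
        raise ValueError(
            f"{n_species} species cannot be separated by "
            f">= {MIN_SEPARATION_HZ} Hz within the bird band"
        )
    rng = np.random.default_rng(seed)
    mid = 0.5 * (usable_lo + usable_hi)
    s = separation_scale
    specs = []
    for i in range(n_species):
        # all between-species differences shrink with separation_scale, so
        # at 0 every species is acoustically identical
        u = rng.random(5)
        center = mid + (usable_lo + i * step - mid) * s
        offset = 1375.0 + (u[0] - 0.5) * 350.0 * s
        second = center + offset
        if second >= usable_hi:
            second = center - offset
        second = float(np.clip(second, BAND_LOW_HZ + 50.0, BAND_HIGH_HZ - 50.0))
        dur_lo = 0.08 + (u[1] - 0.5) * 0.04 * s
        dur_hi = dur_lo + 0.085 + (u[2] - 0.5) * 0.05 * s
        slope = 3500.0 + (u[3] - 0.5) * 3000.0 * s
        specs.append(
            SpeciesSpec(
                name=f"species_{i:02d}",
                basis_freqs=(float(center), second),
                basis_widths=(120.0, 150.0),
                syllable_duration_range=(float(dur_lo), float(dur_hi)),
                syllable_rate=float(2.75 + (u[4] - 0.5) * 1.5 * s),
                chirp_slope_range=(-slope, slope),
            )
        )
    return specs


def synth_recording(
    spec: SpeciesSpec,
    duration: float = DEFAULT_DURATION_S,
    noise_db: float = DEFAULT_NOISE_DB,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | None = None,
) -> tuple[AudioSignal, list[SyllableSegment]]:
    """Synthesize one recording and its true syllable boundaries.

    Syllables (amplitude-enveloped linear chirps at the species' basis
    frequencies) are placed at exponentially distributed gaps; white noise is
    added at ``noise_db`` dB SNR, with signal power measured on the syllables
    and noise power on its in-band (1-10.5 kHz) fraction. ``noise_db=inf``
    gives a clean recording.

    Boundaries are returned on the standard analysis frame grid (10 ms
    shift). A syllable is, by the pulse model the segmenter assumes, the
    region where the signal stays within 20 dB of the syllable's peak, so
    the reported boundaries are the -20 dB points of the raised-cosine
    envelope, not its mathematical support (whose tails are inaudible).
    """
    lo_dur, _ = spec.syllable_duration_range
    if duration < lo_dur:
        raise ValueError("duration must fit at least one syllable")
    rng = np.random.default_rng(seed)
    n = int(duration * sample_rate)
    x = np.zeros(n)
    hop = int(DEFAULT_SHIFT_S * sample_rate)
    segments: list[SyllableSegment] = []
    t = rng.exponential(0.3 / spec.syllable_rate) + 0.02
    while True:
        dur = rng.uniform(*spec.syllable_duration_range)
        if t + dur > duration - 0.01:
            break
        start = int(t * sample_rate)
        length = int(dur * sample_rate)
        tt = np.arange(length) / sample_rate
        envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(length) + 0.5) / length))
        syll = np.zeros(length)
        for f0 in spec.basis_freqs:
            slope = rng.uniform(*spec.chirp_slope_range)
            # keep the instantaneous frequency inside the band
            f_end = np.clip(f0 + slope * dur, BAND_LOW_HZ + 50, BAND_HIGH_HZ - 50)
            eff_slope = (f_end - f0) / dur
            phase = 2.0 * np.pi * (f0 * tt + 0.5 * eff_slope * tt**2)
            syll += np.sin(phase + rng.uniform(0, 2 * np.pi))
        amp = 0.6 + 0.4 * rng.random()
        x[start : start + length] += amp * envelope * syll
        # -20 dB point of the raised-cosine envelope:
        # 0.5 (1 - cos(2 pi t / L)) = 0.1  =>  t = L arccos(0.8) / (2 pi)
        edge = length * np.arccos(0.8) / (2.0 * np.pi)
        start_frame = int(round((start + edge) / hop))
        end_frame = max(start_frame + 1, int(round((start + length - edge) / hop)))
        segments.append(SyllableSegment(start_frame, end_frame, 0.0))
        t += dur + max(0.06, rng.exponential(1.0 / spec.syllable_rate))
    if np.isfinite(noise_db):
        active = np.abs(x) > 0
        sig_power = float(np.mean(x[active] ** 2)) if active.any() else 1.0
        band_frac = (BAND_HIGH_HZ - BAND_LOW_HZ) / (sample_rate / 2.0)
        noise_power = sig_power / (10.0 ** (noise_db / 10.0))
        sigma = np.sqrt(noise_power / band_frac)
        x = x + sigma * rng.standard_normal(n)
    # merge boundaries that touch on the frame grid (rare with min gap 60 ms)
    merged: list[SyllableSegment] = []
    for seg in segments:
        if merged and seg.start_frame < merged[-1].end_frame:
            prev = merged.pop()
            seg = SyllableSegment(prev.start_frame, seg.end_frame, 0.0)
        merged.append(seg)
    return AudioSignal(x, sample_rate), merged


def make_dataset(
    n_species: int = DEFAULT_N_SPECIES,
    n_per_species: int = DEFAULT_N_PER_SPECIES,
    duration: float = DEFAULT_DURATION_S,
    noise_db: float = DEFAULT_NOISE_DB,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | None = None,
    separation_scale: float = 1.0,
) -> SyntheticDataset:
    """Generate a full labeled dataset; a pure function of its arguments."""
    specs = make_species_specs(n_species, seed=seed, separation_scale=separation_scale)
    root = np.random.SeedSequence(seed)
    rec_seeds = root.spawn(n_species * n_per_species)
    recordings = []
    i = 0
    for spec in specs:
        for _ in range(n_per_species):
            rec_seed = int(rec_seeds[i].generate_state(1)[0] % (2**31))
            sig, segs = synth_recording(
                spec, duration=duration, noise_db=noise_db,
                sample_rate=sample_rate, seed=rec_seed,
            )
            recordings.append((sig, spec.name, segs))
            i += 1
    return SyntheticDataset(recordings, specs, seed)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write WAV files plus a manifest CSV (path, species, boundaries).

    Boundaries are encoded as semicolon-separated ``start-end`` frame pairs.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (sig, label, segs) in enumerate(dataset.recordings):
        rec_id = f"rec_{i:04d}"
        wav_path = out_dir / f"{rec_id}.wav"
        write_audio(wav_path, sig)
        rows.append(
            {
                "recording_id": rec_id,
                "path": wav_path.name,
                "species": label,
                "boundaries": ";".join(
                    f"{s.start_frame}-{s.end_frame}" for s in segs
                ),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Load a dataset manifest, resolving WAV paths against its directory."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    df["path"] = [str(manifest_path.parent / p) for p in df["path"]]
    return df


def planted_factorization(
    F: int,
    K: int,
    T: int,
    noise_level: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A rank-K matrix with known factors for NMF verification.

    W0 columns are distinct Gaussian spectral bumps spread over the F bins;
    H0 is sparse non-negative with every basis vector active in several
    frames; V = (W0 H0) perturbed by multiplicative log-normal noise of
    scale ``noise_level`` (exact at 0).
    """
    if K > min(F, T):
        raise ValueError("require K <= min(F, T)")
    rng = np.random.default_rng(seed)
    centers = np.linspace(0.12 * F, 0.88 * F, K)
    width = max(F / (4.0 * K), 1.0)
    bins = np.arange(F)[:, None]
    W0 = np.exp(-0.5 * ((bins - centers[None, :]) / width) ** 2)
    H0 = np.where(rng.random((K, T)) < 0.25, rng.gamma(2.0, 1.0, (K, T)), 0.0)
    # guarantee every basis vector appears in at least 3 frames
    for k in range(K):
        if np.count_nonzero(H0[k]) < 3:
            cols = rng.choice(T, size=3, replace=False)
            H0[k, cols] = rng.gamma(2.0, 1.0, 3)
    V = W0 @ H0
    if noise_level > 0:
        V = V * np.exp(noise_level * rng.standard_normal(V.shape))
    return V, W0, H0
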