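"""Temporal feature integration: collapse each syllable's frame-level feature
sequence into one segmental vector of per-column statistics (mean, population
standard deviation, moment skewness), ordered statistic-major: all means,
then all standard deviations, then all skewnesses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import ShortTimeFeatures
from .preprocess import SyllableSegment


@dataclass
class SegmentalFeature:
    """One vector per syllable: 3*D statistics of its short-time features."""

    vector: np.ndarray
    segment: SyllableSegment
    label: str | None = None
    layout: list[str] | None = None


def skewness(x) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) with central moments; 0 when m2 = 0."""
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    if m2 == 0:
        return 0.0
    m3 = np.mean((x - mu) ** 3)
    return float(m3 / m2**1.5)


def _column_stats(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=0)
    centered = block - mu
    m2 = np.mean(centered**2, axis=0)
    m3 = np.mean(centered**3, axis=0)
    std = np.sqrt(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
    return np.concatenate([mu, std, skew])


def integrate_segment(
    feats: ShortTimeFeatures, seg: SyllableSegment, label: str | None = None
) -> SegmentalFeature:
    """Segmental statistics of the frames in [seg.start_frame, seg.end_frame).

    A one-frame segment yields the frame itself as means with zero standard
    deviations and skewnesses. The statistics are frame-order invariant.
    """
    if seg.end_frame > feats.n_frames:
        raise IndexError(
            f"segment [{seg.start_frame}, {seg.end_frame}) exceeds "
            f"{feats.n_frames} frames"
        )
    block = feats.X[seg.start_frame : seg.end_frame]
    layout = (
        [f"mean_{c}" for c in feats.layout]
        + [f"std_{c}" for c in feats.layout]
        + [f"skew_{c}" for c in feats.layout]
    )
    return SegmentalFeature(_column_stats(block), seg, label=label, layout=layout)
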