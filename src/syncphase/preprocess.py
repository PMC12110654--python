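"""Magnitude, z-score normalization and moving-average smoothing.

The pipeline collapses the three axes into the Euclidean norm, z-scores
the norm over the whole trimmed recording (removing individual
differences in movement amplitude from head size or speaking style), and
smooths with an 11-sample (100 ms at 100 Hz) moving average to suppress
high-frequency sensor noise before peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError, ValidationError
from .io_accel import AccelTrace

__all__ = [
    "MagnitudeTrace",
    "NormalizedTrace",
    "SmoothedTrace",
    "magnitude",
    "zscore",
    "smooth",
]


@dataclass(frozen=True)
class MagnitudeTrace:
    """Euclidean norm of the acceleration vector at each sample."""

    timestamps: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NormalizedTrace:
    """Z-scored magnitude; mean/SD computed over the full trace."""

    timestamps: np.ndarray
    values: np.ndarray
    source_mean: float
    source_sd: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SmoothedTrace:
    """Moving-average-smoothed normalized magnitude.

    ``window_samples`` consecutive samples are averaged; the output is
    shorter than its input by ``window_samples - 1``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    window_samples: int

    def __len__(self) -> int:
        return len(self.values)


def magnitude(trace: AccelTrace) -> MagnitudeTrace:
    """Per-sample Euclidean norm sqrt(ax^2 + ay^2 + az^2)."""
    values = np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)
    return MagnitudeTrace(timestamps=trace.timestamps.copy(), values=values)


def zscore(mag: MagnitudeTrace) -> NormalizedTrace:
    """Z-score the magnitude over the entire (trimmed) recording.

    Uses the sample standard deviation (divisor T-1).  The statistics
    are computed on the trimmed active window only, since the recording
    is defined by its start/end markers.

    Raises
    ------
    DegenerateSignalError
        Constant signal (zero variance).
    ValidationError
        Fewer than two samples.
    """
    if len(mag) < 2:
        raise ValidationError("z-score requires at least 2 samples")
    mean = float(np.mean(mag.values))
    sd = float(np.std(mag.values, ddof=1))
    if sd == 0.0:
        raise DegenerateSignalError("constant signal: zero variance")
    return NormalizedTrace(
        timestamps=mag.timestamps.copy(),
        values=(mag.values - mean) / sd,
        source_mean=mean,
        source_sd=sd,
    )


def smooth(
    norm: NormalizedTrace, window_samples: int = 11, *, centered: bool = False
) -> SmoothedTrace:
    """Moving average over ``window_samples`` consecutive samples.

    The window is forward (causal): output i averages input samples
    i .. i+window-1 and keeps input timestamp i.  Trailing samples with
    incomplete windows are dropped, so the output is shorter by
    window-1.  Because both members of a dyad are smoothed identically,
    the common shift cancels in every pairwise phase difference;
    ``centered=True`` re-anchors the timestamp at the window midpoint
    for users who want shift-free single-trace timings.

    Raises
    ------
    ValidationError
        Trace shorter than the window.
    """
    w = int(window_samples)
    if w < 1:
        raise ValidationError("window_samples must be >= 1")
    n = len(norm)
    if n < w:
        raise ValidationError(f"trace length {n} shorter than window {w}")
    values = np.convolve(norm.values, np.full(w, 1.0 / w), mode="valid")
    if centered:
        timestamps = norm.timestamps[(w - 1) // 2 : (w - 1) // 2 + len(values)]
    else:
        timestamps = norm.timestamps[: len(values)]
    return SmoothedTrace(
        timestamps=timestamps.copy(), values=values, window_samples=w
    )
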