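"""Detection of communicative movement peaks.

A peak is an interior sample of the smoothed normalized magnitude that
is strictly greater than both neighbors and at least the amplitude
threshold (default 2.0, i.e. two standard deviations above the
recording's mean movement level).  The strict-inequality reading means
plateaus of exactly equal samples are never peaks; on real float-valued
data such plateaus have measure zero.  No refractory period is imposed:
the smoothing window already separates genuine movement events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .preprocess import SmoothedTrace

__all__ = ["PeakTrain", "detect_peaks"]

DEFAULT_THRESHOLD = 2.0


@dataclass(frozen=True)
class PeakTrain:
    """Ordered timestamps and amplitudes of detected movement peaks."""

    participant_id: str
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))
        object.__setattr__(
            self, "peak_amplitudes", np.asarray(self.peak_amplitudes, dtype=float)
        )
        if len(self.peak_times) != len(self.peak_amplitudes):
            raise ValidationError("peak_times and peak_amplitudes must match")
        if len(self.peak_times) >= 2 and not np.all(np.diff(self.peak_times) > 0):
            raise ValidationError("peak_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.peak_times, "amplitude": self.peak_amplitudes}
        ).to_csv(path, index=False)


def detect_peaks(
    sm: SmoothedTrace,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    participant_id: str = "",
) -> PeakTrain:
    """Find strict local maxima with amplitude >= threshold.

    Endpoints are never peaks.  An empty train is a valid result.

    Raises
    ------
    ValidationError
        Fewer than 3 samples (no interior sample exists).
    """
    v = sm.values
    if len(v) < 3:
        raise ValidationError("peak detection requires at least 3 samples")
    interior = v[1:-1]
    is_peak = (interior > v[:-2]) & (interior > v[2:]) & (interior >= threshold)
    idx = np.flatnonzero(is_peak) + 1
    return PeakTrain(
        participant_id=participant_id,
        peak_times=sm.timestamps[idx],
        peak_amplitudes=v[idx],
        threshold=threshold,
    )
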