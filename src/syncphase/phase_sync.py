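"""Pairing speaker and listener peaks into signed phase differences.

Each speaker peak is matched to the nearest listener peak; the pair
contributes a signed lag (listener time minus speaker time, in ms) if it
falls within a ±1.0 s window.  Positive lags mean the listener follows
the speaker — the backchannel direction.  Matching is one-to-one by
default: a listener peak is claimed by at most one speaker peak, with
conflicts resolved greedily in ascending absolute offset, so a single
listener nod cannot inflate the event count against several speaker
peaks.  Exact ties between a preceding and a following listener peak
break toward positive lag (listener-follows).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .peaks import PeakTrain

__all__ = [
    "PhaseDiffSet",
    "PhaseHistogram",
    "match_peaks",
    "histogram",
    "central_mass",
]

DEFAULT_WINDOW_S = 1.0
DEFAULT_BIN_MS = 100.0


@dataclass(frozen=True)
class PhaseDiffSet:
    """Signed listener-minus-speaker lags (ms) for one dyad session."""

    dyad_id: str
    diffs_ms: np.ndarray
    window_ms: float = 1000.0
    duration_min: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "diffs_ms", np.asarray(self.diffs_ms, dtype=float))
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be positive")
        if len(self.diffs_ms) and np.max(np.abs(self.diffs_ms)) > self.window_ms:
            raise ValidationError("phase differences exceed the matching window")

    def __len__(self) -> int:
        return len(self.diffs_ms)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"diff_ms": self.diffs_ms}).to_csv(path, index=False)


@dataclass(frozen=True)
class PhaseHistogram:
    """Relative-frequency histogram of phase differences in fixed bins."""

    bin_edges_ms: np.ndarray
    rel_freq: np.ndarray
    n_events: int
    is_empty: bool

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "bin_left_ms": self.bin_edges_ms[:-1],
                "bin_right_ms": self.bin_edges_ms[1:],
                "rel_freq": self.rel_freq,
            }
        ).to_csv(path, index=False)


def _nearest_listener(t: float, listener_times: np.ndarray) -> int:
    """Index of the listener peak nearest to t; ties prefer the later
    (positive-lag) peak."""
    j = int(np.searchsorted(listener_times, t))
    if j == 0:
        return 0
    if j == len(listener_times):
        return j - 1
    before, after = listener_times[j - 1], listener_times[j]
    # tie (equal |offset|) breaks toward the following peak
    if (after - t) <= (t - before):
        return j
    return j - 1


def match_peaks(
    speaker: PeakTrain,
    listener: PeakTrain,
    window_s: float = DEFAULT_WINDOW_S,
    *,
    matching: str = "one_to_one",
    dyad_id: str = "",
    duration_min: float = 1.0,
) -> PhaseDiffSet:
    """Match speaker peaks to nearest listener peaks within ±window_s.

    Parameters
    ----------
    matching
        ``"one_to_one"`` (default): each listener peak may be claimed by
        at most one speaker peak; when two speaker peaks share a nearest
        listener peak the smaller absolute offset wins (ties toward
        positive lag), and the loser contributes nothing.
        ``"many_to_one"``: every speaker peak keeps its nearest listener
        peak regardless of sharing (the permissive reading).
    duration_min
        Analyzed duration in minutes, carried for the density feature.

    Returns
    -------
    PhaseDiffSet
        Signed lags in ms, ordered by speaker peak time.
    """
    if matching not in ("one_to_one", "many_to_one"):
        raise ValidationError(f"unknown matching mode {matching!r}")
    st, lt = speaker.peak_times, listener.peak_times
    if len(st) == 0 or len(lt) == 0:
        return PhaseDiffSet(dyad_id, np.empty(0), window_ms=window_s * 1000.0,
                            duration_min=duration_min)

    candidates = []  # (|offset_s|, tie_rank, speaker_idx, listener_idx, diff_ms)
    for i, t in enumerate(st):
        j = _nearest_listener(t, lt)
        offset = lt[j] - t
        if abs(offset) <= window_s:
            tie_rank = 0 if offset > 0 else 1  # positive lag wins exact ties
            candidates.append((abs(offset), tie_rank, i, j, offset * 1000.0))

    if matching == "many_to_one":
        chosen = candidates
    else:
        chosen = []
        claimed: set[int] = set()
        for cand in sorted(candidates):
            if cand[3] not in claimed:
                claimed.add(cand[3])
                chosen.append(cand)

    chosen.sort(key=lambda c: c[2])  # back to speaker order
    diffs = np.array([c[4] for c in chosen])
    return PhaseDiffSet(
        dyad_id, diffs, window_ms=window_s * 1000.0, duration_min=duration_min
    )


def histogram(pd_set: PhaseDiffSet, bin_ms: float = DEFAULT_BIN_MS) -> PhaseHistogram:
    """Relative-frequency histogram over [-window, +window].

    Bins are left-closed right-open except the last, which is closed, so
    a lag of exactly +window lands in the final bin.  Frequencies are
    normalized by the event count; an empty set yields all zeros with
    ``is_empty=True``.
    """
    w = pd_set.window_ms
    n_bins = 2 * w / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError("bin_ms must divide the full window evenly")
    edges = -w + bin_ms * np.arange(int(round(n_bins)) + 1)
    n = len(pd_set)
    if n == 0:
        return PhaseHistogram(edges, np.zeros(len(edges) - 1), 0, True)
    counts, _ = np.histogram(pd_set.diffs_ms, bins=edges)
    return PhaseHistogram(edges, counts / n, n, False)


def central_mass(
    pd_set: PhaseDiffSet,
    halfwidth_ms: float = 300.0,
    center: str | float = "mean",
) -> float:
    """Fraction of lags within ±halfwidth of the center.

    ``center`` is the distribution mean (default), ``"zero"``, or an
    explicit value in ms.  Quantifies how concentrated the synchrony
    events are around the dyad's typical lag.
    """
    if len(pd_set) == 0:
        raise ValidationError("central_mass undefined for an empty set")
    if center == "mean":
        c = float(np.mean(pd_set.diffs_ms))
    elif center == "zero":
        c = 0.0
    else:
        c = float(center)
    return float(np.mean(np.abs(pd_set.diffs_ms - c) <= halfwidth_ms))
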