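"""Distribution-based synchrony features of a dyad session.

Four per-dyad metrics summarize the phase-difference distribution:

density (synchrony activity)
    Matched events per minute of interaction.
mean (synchrony directionality)
    Mean signed lag in ms; positive = listener follows speaker.
SD (synchrony variability)
    Sample standard deviation of the lags; temporal precision.
kurtosis (synchrony coherence)
    Excess kurtosis of the lag distribution (normal = 0); concentration
    of events around the typical lag.

Features with insufficient events are reported as NaN, never as 0: a
dyad with one matched event has a mean but no variability, and kurtosis
needs at least four events.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .phase_sync import PhaseDiffSet

__all__ = ["SynchronyFeatures", "compute_features", "features_table"]


@dataclass(frozen=True)
class SynchronyFeatures:
    """The four per-dyad synchrony metrics plus session metadata."""

    dyad_id: str
    n_events: int
    duration_min: float
    density_per_min: float
    mean_ms: float
    sd_ms: float
    kurtosis_excess: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _kurtosis(d: np.ndarray, mode: str) -> float:
    """Kurtosis of d under the selected convention.

    ``excess``     bias-corrected sample excess kurtosis (normal -> 0)
    ``raw``        bias-corrected, not excess (normal -> 3)
    ``population`` biased excess (plain fourth-moment ratio minus 3)
    """
    if mode == "excess":
        return float(stats.kurtosis(d, fisher=True, bias=False))
    if mode == "raw":
        return float(stats.kurtosis(d, fisher=False, bias=False))
    if mode == "population":
        return float(stats.kurtosis(d, fisher=True, bias=True))
    raise ValidationError(f"unknown kurtosis mode {mode!r}")


def compute_features(
    pd_set: PhaseDiffSet, *, kurtosis_mode: str = "excess"
) -> SynchronyFeatures:
    """Compute the four synchrony features from a phase-difference set.

    Density divides the event count by the trimmed-window duration (not
    the first-to-last-peak span).  SD uses divisor n-1.  The kurtosis
    default is bias-corrected excess kurtosis; ``kurtosis_mode`` selects
    ``"raw"`` or ``"population"`` variants.  Degenerate cases (zero
    variance with the bias-corrected estimator) are NaN.
    """
    d = pd_set.diffs_ms
    n = len(d)
    density = n / pd_set.duration_min
    mean_ms = float(np.mean(d)) if n >= 1 else math.nan
    sd_ms = float(np.std(d, ddof=1)) if n >= 2 else math.nan
    if n >= 4 and np.std(d) > 0:
        kurt = _kurtosis(d, kurtosis_mode)
    else:
        kurt = math.nan
    return SynchronyFeatures(
        dyad_id=pd_set.dyad_id,
        n_events=n,
        duration_min=pd_set.duration_min,
        density_per_min=density,
        mean_ms=mean_ms,
        sd_ms=sd_ms,
        kurtosis_excess=kurt,
    )


def features_table(
    feats: Iterable[SynchronyFeatures],
    groups: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Combine per-dyad features into one table (one row per dyad)."""
    rows = [asdict(f) for f in feats]
    df = pd.DataFrame(
        rows,
        columns=[
            "dyad_id",
            "n_events",
            "duration_min",
            "density_per_min",
            "mean_ms",
            "sd_ms",
            "kurtosis_excess",
        ],
    )
    if groups is not None:
        df.insert(1, "group", list(groups))
    return df
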