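"""Reading, writing and validating triaxial accelerometer recordings.

A recording is a regularly sampled (nominally 100 Hz) triaxial acceleration
series for one participant, stored as a CSV with a time column and three
axis columns.  A *session manifest* pairs a speaker file with a listener
file, carries the dyad's group label (TD or ASD condition) and the active
recording window (delimited in the original protocol by synchronization
claps), plus optional covariates such as AQ scores and Likert ratings.

Acceleration units (g or m/s^2) are carried but never converted: the
downstream z-score normalization makes every result unit-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import SessionRejectedError, ValidationError

__all__ = [
    "AccelTrace",
    "SessionManifest",
    "read_trace",
    "write_trace",
    "trim_to_window",
    "check_missing",
    "read_manifest",
    "write_manifest",
]

DEFAULT_COLUMNS: Mapping[str, str] = {
    "time": "time",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
}


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled triaxial acceleration series for one participant.

    Parameters
    ----------
    participant_id
        Free-text identifier.
    timestamps
        Strictly increasing sample times in seconds.
    ax, ay, az
        Per-axis acceleration, same length as ``timestamps``.  Units are
        whatever the sensor emitted (typically g); they are carried,
        never converted.
    sample_rate_hz
        Nominal sampling rate (100 for the sensors this package targets).
    missing_fraction
        Fraction of expected samples that were absent or NaN beyond the
        short-gap interpolation limit (set by :func:`check_missing`).
    """

    participant_id: str
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float = 100.0
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("timestamps", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.timestamps)
        if any(len(getattr(self, a)) != n for a in ("ax", "ay", "az")):
            raise ValidationError("axis arrays must match timestamp length")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class SessionManifest:
    """One dyad session: file pairing, group label and recording window."""

    dyad_id: str
    group_label: str
    speaker_file: str
    listener_file: str
    start_time_s: float
    end_time_s: float
    covariates: dict = field(default_factory=dict)

    VALID_GROUPS = ("TD", "ASD")

    def __post_init__(self) -> None:
        if self.group_label not in self.VALID_GROUPS:
            raise ValidationError(
                f"group_label must be one of {self.VALID_GROUPS}, got {self.group_label!r}"
            )
        if not self.end_time_s > self.start_time_s:
            raise ValidationError("end_time_s must exceed start_time_s")


def _detect_time_unit(time_values: np.ndarray) -> str:
    """Heuristic: 100 Hz sensors tick every 0.01 s or every 10 ms.

    A median inter-sample interval above 0.5 is implausible in seconds
    for this class of recording, so it is read as milliseconds.
    """
    if len(time_values) < 2:
        return "s"
    dt = float(np.median(np.diff(time_values)))
    return "ms" if dt > 0.5 else "s"


def read_trace(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    time_unit: str = "auto",
    participant_id: str | None = None,
    sample_rate_hz: float | None = None,
) -> AccelTrace:
    """Read a triaxial accelerometer CSV into an :class:`AccelTrace`.

    Parameters
    ----------
    path
        CSV with a header row.
    column_map
        Maps the logical names ``time, ax, ay, az`` to the file's column
        names.  Defaults to identity (``time,ax,ay,az``).
    time_unit
        ``"s"``, ``"ms"``, or ``"auto"`` (magnitude heuristic).
    sample_rate_hz
        Nominal rate; inferred from the median sampling interval when
        omitted.

    Raises
    ------
    ValidationError
        Missing columns or non-monotone timestamps.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")

    t = df[cols["time"]].to_numpy(dtype=float)
    if time_unit == "auto":
        time_unit = _detect_time_unit(t)
    if time_unit == "ms":
        t = t / 1000.0
    elif time_unit != "s":
        raise ValidationError(f"unknown time_unit {time_unit!r}")

    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{path}: timestamps are not strictly increasing")
    if sample_rate_hz is None:
        if len(t) >= 2:
            sample_rate_hz = float(round(1.0 / np.median(np.diff(t))))
        else:
            sample_rate_hz = 100.0

    return AccelTrace(
        participant_id=participant_id or path.stem,
        timestamps=t,
        ax=df[cols["ax"]].to_numpy(dtype=float),
        ay=df[cols["ay"]].to_numpy(dtype=float),
        az=df[cols["az"]].to_numpy(dtype=float),
        sample_rate_hz=sample_rate_hz,
    )


def write_trace(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace as ``time,ax,ay,az`` CSV (seconds, full precision)."""
    df = pd.DataFrame(
        {"time": trace.timestamps, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def trim_to_window(trace: AccelTrace, start_s: float, end_s: float) -> AccelTrace:
    """Keep samples with ``start_s <= t < end_s`` (half-open window).

    The half-open convention makes adjacent window durations additive.
    Downstream event densities divide by ``end_s - start_s``, not by the
    span of surviving samples.
    """
    if not end_s > start_s:
        raise ValidationError(f"empty window [{start_s}, {end_s})")
    mask = (trace.timestamps >= start_s) & (trace.timestamps < end_s)
    if not mask.any():
        raise ValidationError(
            f"window [{start_s}, {end_s}) does not overlap trace support"
        )
    return replace(
        trace,
        timestamps=trace.timestamps[mask],
        ax=trace.ax[mask],
        ay=trace.ay[mask],
        az=trace.az[mask],
    )


def check_missing(
    trace: AccelTrace,
    max_missing_fraction: float = 0.05,
    *,
    max_gap_interp: int = 3,
) -> AccelTrace:
    """Validate sampling completeness and repair short gaps.

    The trace is laid onto the uniform grid implied by its nominal rate.
    Samples that are absent from the grid or NaN form gaps.  Gaps of at
    most ``max_gap_interp`` consecutive samples (30 ms at 100 Hz, below
    the smoothing window) are linearly interpolated and do not count as
    missing.  Longer gaps count toward the missing fraction; if that
    fraction exceeds ``max_missing_fraction`` the session is rejected,
    otherwise the long gaps are filled as well so downstream code always
    sees a complete regular grid.

    Raises
    ------
    SessionRejectedError
        Missing fraction above threshold (carries the fraction).
    ValidationError
        Samples that do not align with the nominal grid.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValidationError("max_missing_fraction must be in [0, 1]")
    n = len(trace)
    if n < 2:
        return trace
    dt = 1.0 / trace.sample_rate_hz
    t0 = trace.timestamps[0]
    idx_f = (trace.timestamps - t0) / dt
    idx = np.rint(idx_f).astype(int)
    if np.max(np.abs(idx_f - idx)) > 0.25:
        raise ValidationError("timestamps do not align with the nominal sampling grid")
    n_expected = idx[-1] + 1

    full = np.full((3, n_expected), np.nan)
    for k, axis in enumerate((trace.ax, trace.ay, trace.az)):
        full[k, idx] = axis
    nan_mask = np.isnan(full).any(axis=0)

    # contiguous NaN runs
    missing_beyond_limit = 0
    if nan_mask.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], nan_mask.view(np.int8), [0]))))
        starts, stops = edges[::2], edges[1::2]
        for s, e in zip(starts, stops):
            if e - s > max_gap_interp:
                missing_beyond_limit += e - s
    fraction = missing_beyond_limit / n_expected
    if fraction > max_missing_fraction:
        raise SessionRejectedError(fraction, max_missing_fraction)

    grid_t = t0 + dt * np.arange(n_expected)
    if nan_mask.any():
        good = ~nan_mask
        for k in range(3):
            full[k, nan_mask] = np.interp(grid_t[nan_mask], grid_t[good], full[k, good])

    return replace(
        trace,
        timestamps=grid_t,
        ax=full[0],
        ay=full[1],
        az=full[2],
        missing_fraction=fraction,
    )


def read_manifest(path: str | Path) -> list[SessionManifest]:
    """Read a YAML or JSON session manifest.

    The file holds a list of mappings with the :class:`SessionManifest`
    fields (``group`` is accepted as an alias for ``group_label``).
    Relative trace paths are resolved against the manifest's directory.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        entries = json.loads(text)
    else:
        entries = yaml.safe_load(text)
    if isinstance(entries, Mapping) and "sessions" in entries:
        entries = entries["sessions"]
    if not isinstance(entries, Sequence):
        raise ValidationError(f"{path}: manifest must be a list of sessions")
    sessions = []
    for e in entries:
        e = dict(e)
        group = e.pop("group_label", None) or e.pop("group", None)
        for key in ("speaker_file", "listener_file"):
            p = Path(e[key])
            if not p.is_absolute():
                e[key] = str(path.parent / p)
        sessions.append(
            SessionManifest(
                dyad_id=str(e["dyad_id"]),
                group_label=group,
                speaker_file=e["speaker_file"],
                listener_file=e["listener_file"],
                start_time_s=float(e["start_time_s"]),
                end_time_s=float(e["end_time_s"]),
                covariates=dict(e.get("covariates") or {}),
            )
        )
    return sessions


def write_manifest(sessions: Sequence[SessionManifest], path: str | Path) -> None:
    """Write sessions as a YAML manifest (paths stored as given)."""
    payload = [
        {
            "dyad_id": s.dyad_id,
            "group_label": s.group_label,
            "speaker_file": s.speaker_file,
            "listener_file": s.listener_file,
            "start_time_s": s.start_time_s,
            "end_time_s": s.end_time_s,
            "covariates": s.covariates,
        }
        for s in sessions
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
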