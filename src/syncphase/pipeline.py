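"""End-to-end orchestration: trace pair -> features, corpus -> table.

This is the library face of the pipeline; the CLI wraps these functions
without adding logic.  Defaults are the method's canonical constants
(2.0 amplitude threshold, ±1.0 s matching window, 11-sample smoothing,
100 ms histogram bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import SyncphaseError
from .features import SynchronyFeatures, compute_features, features_table
from .io_accel import (
    AccelTrace,
    SessionManifest,
    check_missing,
    read_manifest,
    read_trace,
    trim_to_window,
)
from .peaks import PeakTrain, detect_peaks
from .phase_sync import PhaseDiffSet, histogram, match_peaks
from .preprocess import magnitude, smooth, zscore
from .simulate import DyadRecord

logger = logging.getLogger("syncphase")

__all__ = ["RunConfig", "SessionResult", "process_trace", "analyze_session",
           "analyze_records", "analyze_corpus"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved analysis parameters for a run."""

    threshold: float = 2.0
    window_s: float = 1.0
    smooth_samples: int = 11
    bin_ms: float = 100.0
    matching: str = "one_to_one"
    kurtosis_mode: str = "excess"
    centered_smoothing: bool = False
    max_missing_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.threshold, self.window_s, self.smooth_samples, self.bin_ms) <= 0:
            raise SyncphaseError("all numeric RunConfig parameters must be positive")


@dataclass
class SessionResult:
    """Per-dyad analysis output."""

    manifest: SessionManifest
    speaker_peaks: PeakTrain
    listener_peaks: PeakTrain
    phase_diffs: PhaseDiffSet
    features: SynchronyFeatures


def process_trace(
    trace: AccelTrace,
    start_s: float,
    end_s: float,
    config: RunConfig = RunConfig(),
    *,
    validate_missing: bool = True,
) -> PeakTrain:
    """Run one trace through trim -> magnitude -> z-score -> smooth -> peaks."""
    trimmed = trim_to_window(trace, start_s, end_s)
    if validate_missing:
        trimmed = check_missing(trimmed, config.max_missing_fraction)
    sm = smooth(
        zscore(magnitude(trimmed)),
        config.smooth_samples,
        centered=config.centered_smoothing,
    )
    return detect_peaks(sm, config.threshold, participant_id=trace.participant_id)


def analyze_session(
    manifest: SessionManifest,
    config: RunConfig = RunConfig(),
    *,
    speaker: AccelTrace | None = None,
    listener: AccelTrace | None = None,
) -> SessionResult:
    """Analyze one dyad session (from files, or from in-memory traces)."""
    if speaker is None:
        speaker = read_trace(manifest.speaker_file, participant_id=f"{manifest.dyad_id}_speaker")
    if listener is None:
        listener = read_trace(manifest.listener_file, participant_id=f"{manifest.dyad_id}_listener")
    s_peaks = process_trace(speaker, manifest.start_time_s, manifest.end_time_s, config)
    l_peaks = process_trace(listener, manifest.start_time_s, manifest.end_time_s, config)
    duration_min = (manifest.end_time_s - manifest.start_time_s) / 60.0
    pd_set = match_peaks(
        s_peaks, l_peaks, config.window_s,
        matching=config.matching, dyad_id=manifest.dyad_id,
        duration_min=duration_min,
    )
    feats = compute_features(pd_set, kurtosis_mode=config.kurtosis_mode)
    return SessionResult(manifest, s_peaks, l_peaks, pd_set, feats)


def analyze_records(
    records: Sequence[DyadRecord], config: RunConfig = RunConfig()
) -> tuple[pd.DataFrame, list[SessionResult]]:
    """Analyze an in-memory simulated corpus; returns the feature table."""
    results = [
        analyze_session(r.manifest, config, speaker=r.speaker, listener=r.listener)
        for r in records
    ]
    df = features_table(
        [r.features for r in results], [r.manifest.group_label for r in results]
    )
    return df, results


def analyze_corpus(
    manifest_path: str | Path,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[SessionResult], list[tuple[str, str]]]:
    """Analyze every session in a manifest file.

    Per-session failures (unreadable file, rejected for missing data,
    degenerate signal) are logged and skipped; the failure list carries
    (dyad_id, reason).  When ``out_dir`` is given, writes
    ``features.csv``, per-dyad phase-difference and histogram CSVs and
    the failure log there.
    """
    sessions = read_manifest(manifest_path)
    results: list[SessionResult] = []
    failures: list[tuple[str, str]] = []
    for s in sessions:
        try:
            results.append(analyze_session(s, config))
        except (SyncphaseError, OSError) as exc:
            logger.warning("session %s failed: %s", s.dyad_id, exc)
            failures.append((s.dyad_id, str(exc)))
    df = features_table(
        [r.features for r in results], [r.manifest.group_label for r in results]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "features.csv", index=False)
        for r in results:
            r.phase_diffs.to_csv(out / f"{r.manifest.dyad_id}_phase_diffs.csv")
            histogram(r.phase_diffs, config.bin_ms).to_csv(
                out / f"{r.manifest.dyad_id}_histogram.csv"
            )
        log_lines = [f"{d}\t{reason}" for d, reason in failures]
        (out / "excluded_sessions.log").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))
        (out / "run_config.txt").write_text(
            "\n".join(f"{k} = {v}" for k, v in asdict(config).items()) + "\n"
        )
    return df, results, failures
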