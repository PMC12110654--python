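"""Exception hierarchy for syncphase."""


class SyncphaseError(Exception):
    """Base class for all syncphase errors."""


class ValidationError(SyncphaseError):
    """Input data violates a structural contract (non-monotone time,
    mismatched lengths, empty trim window, ...)."""


class SessionRejectedError(SyncphaseError):
    """A recording exceeds the allowed missing-data fraction.

    Carries the measured fraction so callers can log why the session
    was dropped.
    """

    def __init__(self, missing_fraction: float, max_missing_fraction: float):
        self.missing_fraction = float(missing_fraction)
        self.max_missing_fraction = float(max_missing_fraction)
        super().__init__(
            f"session rejected: missing fraction {missing_fraction:.4f} "
            f"exceeds threshold {max_missing_fraction:.4f}"
        )


class DegenerateSignalError(SyncphaseError):
    """A signal or sample has zero variance where variance is required."""
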