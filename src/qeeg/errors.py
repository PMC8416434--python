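"""Exception hierarchy for the qeeg pipeline.

Every stage raises a subclass of :class:`QeegError` so callers can catch
pipeline failures without masking programming errors.
"""


class QeegError(Exception):
    """Base class for all qeeg-specific errors."""


class ChannelMismatchError(QeegError):
    """Input channels cannot be mapped onto the analysis montage."""

    def __init__(self, missing=(), extra=()):
        self.missing = tuple(missing)
        self.extra = tuple(extra)
        parts = []
        if self.missing:
            parts.append(f"missing channels: {', '.join(self.missing)}")
        if self.extra:
            parts.append(f"unexpected channels: {', '.join(self.extra)}")
        super().__init__("; ".join(parts) or "channel mismatch")


class UnsupportedOperationError(QeegError):
    """Requested operation is outside the supported envelope (e.g. upsampling)."""


class InsufficientDataError(QeegError):
    """Recording too short for the requested analysis."""


class InsufficientCleanDataError(InsufficientDataError):
    """Artifact rejection left less than the minimum analyzable duration."""


class UndefinedCoherenceError(QeegError):
    """Coherence undefined: a channel has zero power over every bin of the band."""


class InfeasibleStratificationError(QeegError):
    """A class has fewer members than the number of folds."""


class MetricUndefinedError(QeegError):
    """Fold metric undefined (e.g. single-class test fold)."""


class FitFailureError(QeegError):
    """Model fit failed (degenerate fold, non-convergence at every penalty)."""


class ValidationError(QeegError):
    """Configuration or effect specification references unknown entities."""
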