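"""Exception hierarchy.

Every failure mode of the pipeline raises a subclass of :class:`SonoquantError`
so that callers (and the cohort driver) can distinguish analysis failures from
programming errors.  Diagnostic payloads are attached where a caller may want
to inspect them (e.g. :class:`LoopFitError`).
"""

from __future__ import annotations


class SonoquantError(Exception):
    """Base class for all package-specific failures."""


class SizingError(SonoquantError):
    """A phantom geometry does not fit inside the requested image."""


class AliasingError(SonoquantError):
    """A prescribed velocity exceeds the PRF-implied Nyquist velocity."""


class TrackingError(SonoquantError):
    """Too many low-confidence frames for reliable wall/speckle tracking."""


class BeatSegmentationError(SonoquantError):
    """No cardiac periodicity could be detected in a trace."""


class EnvelopeError(SonoquantError):
    """Doppler spectrogram has too little signal for envelope extraction."""


class LoopFitError(SonoquantError):
    """The diameter-velocity loop fit is unreliable.

    Carries diagnostics so the caller can report why the fit was rejected.
    """

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = dict(diagnostics)


class PeakCountError(SonoquantError):
    """Unexpected number of prominent peaks (e.g. in a mitral inflow trace)."""


class RoiError(SonoquantError):
    """A region of interest is out of bounds, undersized, or uninformative."""


class CohortError(SonoquantError):
    """Cohort assembly or group comparison precondition violated."""
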