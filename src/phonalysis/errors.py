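"""Exception hierarchy for the phonation-analysis pipeline.

Every error raised on bad input or degenerate data derives from
:class:`PhonalysisError`, so batch drivers can catch one base class and
record a per-recording failure status instead of aborting the run.
"""


class PhonalysisError(Exception):
    """Base class for all package errors."""


class InvalidParams(PhonalysisError, ValueError):
    """Synthesis or configuration parameters violate their invariants."""


class InvalidInput(PhonalysisError, ValueError):
    """An analysis operation received audio it cannot process (empty, too short)."""


class NoVoicedSegment(PhonalysisError):
    """No voiced region was detected; the recording is not analyzed."""


class SegmentTooShort(PhonalysisError):
    """The voiced run is too short to survive the transient discard."""


class DegenerateSpectrum(PhonalysisError):
    """A band integral needed for a spectral ratio is zero or negative."""


class InsufficientBandwidth(PhonalysisError):
    """The recording's Nyquist frequency is below the requested analysis fmax."""


class UnvoicedInput(PhonalysisError):
    """Pitch-based analysis found no voiced frame."""


class TooFewCycles(PhonalysisError):
    """Fewer than three glottal cycles detected; jitter/shimmer undefined."""


class InvalidCycles(PhonalysisError):
    """Cycle amplitudes are non-positive; shimmer in dB is undefined."""


class InvalidLabels(PhonalysisError, ValueError):
    """ROC analysis requires at least one case and one control."""


class RankDeficient(PhonalysisError):
    """The regression design matrix is rank deficient."""


class JoinError(PhonalysisError):
    """Feature and metadata tables could not be joined on subject id."""
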