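"""Exception types shared across the package."""


class RespcalError(Exception):
    """Base class for all respcal errors."""


class ChannelMissingError(RespcalError, KeyError):
    """A required named channel is absent from the input file."""


class FormatError(RespcalError, ValueError):
    """The input file violates the expected layout (e.g. non-uniform time axis)."""


class ResamplingError(RespcalError, ValueError):
    """Requested resampling is unsupported (non-integer decimation factor)."""


class EmptyRecordingError(RespcalError, ValueError):
    """Channel alignment left no overlapping samples."""


class InsufficientDataError(RespcalError, ValueError):
    """Signals are too short for the requested design-matrix / delay search."""


class SamplingRateError(RespcalError, ValueError):
    """Model and signal sampling rates disagree."""


class UndefinedMetricError(RespcalError, ZeroDivisionError):
    """A metric denominator (SS_tot, RMS, reference volume) is zero."""


class NoBreathError(RespcalError, ValueError):
    """No breathing-band component found when estimating breathing frequency."""
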