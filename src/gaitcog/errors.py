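"""Exception hierarchy for the gaitcog pipeline."""


class GaitcogError(Exception):
    """Base class for all gaitcog errors."""


class InvalidParameterError(GaitcogError, ValueError):
    """A domain parameter violates its invariant (e.g. non-positive duration)."""


class UnsupportedRateError(GaitcogError, ValueError):
    """Sampling rate cannot be handled (e.g. upsampling requested)."""


class SignalTooShortError(GaitcogError, ValueError):
    """Signal shorter than the minimum an operation needs."""


class InsufficientGaitError(GaitcogError, ValueError):
    """Fewer than two complete gait cycles were found."""


class InvalidEventsError(GaitcogError, ValueError):
    """An event series violates the TO < MSV < HS cycle ordering."""


class FormatError(GaitcogError, ValueError):
    """A recording or table file failed validation on load."""
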