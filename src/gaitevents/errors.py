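"""Exception hierarchy for gaitevents."""


class GaitEventsError(Exception):
    """Base class for all gaitevents errors."""


class FormatError(GaitEventsError):
    """A trial or events file does not conform to the expected CSV dialect."""


class InvalidSpecError(GaitEventsError, ValueError):
    """A filter specification is invalid (e.g. cutoff at or above Nyquist)."""


class InsufficientDataError(GaitEventsError, ValueError):
    """Not enough samples/rows for the requested operation."""


class UndefinedCorrelationError(GaitEventsError, ValueError):
    """Pearson correlation undefined because a column has zero variance."""
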