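"""Exception and warning types shared across the package."""


class CueTradeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConditionError(CueTradeError, ValueError):
    """A stimulus condition that is never presented, e.g. (0 µs, 0 dB)."""


class UndefinedSideError(CueTradeError, ValueError):
    """No correct response side exists (probe trials, (0, 0))."""


class TrialLogError(CueTradeError, ValueError):
    """A trial-log file could not be parsed; the message names the offending row."""


class UnidentifiableDesignError(CueTradeError, ValueError):
    """The stimulus design cannot identify a requested sensitivity parameter."""


class UndefinedTITRError(CueTradeError, ValueError):
    """Trading ratio requested for an observer with zero ITD sensitivity."""


class TrialClassMismatchWarning(UserWarning):
    """A trial log declared a trial class that contradicts the cue signs."""


class QCWarning(UserWarning):
    """Session quality control encountered a degenerate session."""
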