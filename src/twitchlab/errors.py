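"""Exception hierarchy.

All package errors derive from :class:`TwitchlabError` so callers can catch
one base class; the CLI maps validation errors to exit code 1 and stage
failures to exit code 2.
"""


class TwitchlabError(Exception):
    """Base class for all twitchlab errors."""


class InvalidParameterError(TwitchlabError, ValueError):
    """A parameter is outside its documented range."""


class FormatError(TwitchlabError, ValueError):
    """An input file does not conform to the expected table dialect."""


class ConfigError(TwitchlabError, ValueError):
    """A configuration value failed validation; names the key and bound."""


class AlignmentError(TwitchlabError, ValueError):
    """Two series that must share a time base do not."""


class UnrecoverableClockError(TwitchlabError, RuntimeError):
    """Frame clock cannot be repaired (e.g. surplus frames in a gap)."""


class InsufficientDataError(TwitchlabError, ValueError):
    """Too few events/values for the requested computation."""


class EmptyResultError(TwitchlabError, ValueError):
    """An aggregation was requested over zero included elements."""


class StageError(TwitchlabError, RuntimeError):
    """A pipeline stage failed; message carries stage name and cause."""
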