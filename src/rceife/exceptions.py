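"""Exception hierarchy for rceife.

Every error raised by the package derives from :class:`RceIfeError`, so
callers can catch one type at the CLI boundary.
"""


class RceIfeError(Exception):
    """Base class for all rceife errors."""


class FormatError(RceIfeError):
    """Input file does not match the expected delimited-table layout."""


class ParseError(FormatError):
    """A cell that should be numeric failed to parse."""


class LabelError(RceIfeError):
    """Label column is not a valid two-class vector, or a class is absent."""


class IdError(RceIfeError):
    """Duplicate or unknown sample/feature identifier."""


class SplitError(RceIfeError):
    """A stratified split cannot satisfy its class-presence contract."""


class StatisticsError(RceIfeError):
    """A statistical operation received a degenerate input."""


class ParameterError(RceIfeError):
    """A parameter is outside its admissible range."""


class StateError(RceIfeError):
    """An operation was called on an object in the wrong state."""


class MetricError(RceIfeError):
    """A performance metric is undefined for the given input."""


class EngineError(RceIfeError):
    """The elimination loop reached an inconsistent state."""
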