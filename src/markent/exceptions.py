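"""Exception hierarchy.

All errors derive from :class:`MarkentError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin so idiomatic ``except ValueError`` keeps working.
"""


class MarkentError(Exception):
    """Base class for all markent errors."""


class InvalidParameterError(MarkentError, ValueError):
    """A probability, size or flag is outside its admissible range."""


class InsufficientDataError(MarkentError, ValueError):
    """The input sequence is too short for the requested operation."""


class DegenerateChainError(MarkentError, ValueError):
    """The transition matrix has no unique stationary distribution."""


class DegenerateSpectrumError(MarkentError, ValueError):
    """A non-unit eigenvalue lies (numerically) on the unit circle, so the
    geometric-series memory correction diverges."""


class EnumerationTooLargeError(MarkentError, ValueError):
    """L**N exceeds the configured exhaustive-enumeration budget."""


class AlphabetError(MarkentError, ValueError):
    """A symbol cannot be mapped to the integer alphabet."""
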