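"""Exception hierarchy.

Every error raised by this package derives from :class:`ProtnormError`, so
callers can catch one type. Most also derive from :class:`ValueError`
because they signal invalid data or configuration rather than programming
faults.
"""


class ProtnormError(Exception):
    """Base class for all errors raised by protnorm."""


class SchemaError(ProtnormError, ValueError):
    """An input table lacks a required (mapped) column."""


class IntegrityError(ProtnormError, ValueError):
    """A uniqueness or consistency invariant of the data is violated."""


class FormatError(ProtnormError, ValueError):
    """A file does not conform to its declared dialect."""


class DesignError(ProtnormError, ValueError):
    """Sample design and quantification table disagree."""


class DegenerateSampleError(ProtnormError, ValueError):
    """A sample has no usable (positive) abundances."""


class CountError(ProtnormError, ValueError):
    """Inconsistent counts passed to a combinatorial test."""


class ContainmentError(ProtnormError, ValueError):
    """A selection is not contained in its universe."""


class SummaryError(ProtnormError, ValueError):
    """A summary is undefined (e.g. empty regulated set)."""


class ShapeError(ProtnormError, ValueError):
    """A matrix has the wrong shape for the requested operation."""


class MatrixError(ProtnormError, ValueError):
    """A distance matrix is not symmetric/square/zero-diagonal."""


class UndefinedCorrelationError(ProtnormError, ValueError):
    """Pearson distance requested for a zero-variance vector."""


class UnknownLeafError(ProtnormError, KeyError):
    """A leaf identifier is not part of the tree."""


class ConfigError(ProtnormError, ValueError):
    """A configuration is invalid or infeasible."""


class ValidationError(ProtnormError, ValueError):
    """Pipeline configuration failed fail-fast validation."""
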