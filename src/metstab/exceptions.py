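"""Exception hierarchy.

All errors raised by this package derive from :class:`MetstabError` so callers
can catch package errors without masking programming errors.
"""


class MetstabError(Exception):
    """Base class for all metstab errors."""


class ConfigError(MetstabError):
    """A configuration problem: missing column mapping, bad option value."""


class ValidationError(MetstabError):
    """Input data violates a structural invariant (duplicate keys, empty cells)."""


class ParseError(MetstabError):
    """A value in an input file could not be parsed."""


class DesignError(MetstabError):
    """The experimental design does not support the requested analysis."""


class DimensionError(MetstabError):
    """A dimensional requirement is not met (e.g. too few axes or levels)."""


class ConvergenceError(MetstabError):
    """An iterative fit failed to converge; carries a trace summary."""
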