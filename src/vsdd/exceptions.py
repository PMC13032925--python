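"""Exception hierarchy for vsdd.

All library-raised errors derive from :class:`VsddError` so callers can catch
one type at pipeline boundaries. Statistical non-convergence is *not* an
exception (it is reported on the fit object); these classes cover contract
violations only.
"""


class VsddError(Exception):
    """Base class for all vsdd errors."""


class SchemaError(VsddError):
    """An input table is missing a required column."""


class ParseError(VsddError):
    """A cell could not be parsed into its declared type."""


class InvariantError(VsddError):
    """A parsed record violates a domain invariant."""


class ReferentialError(VsddError):
    """A spike row references a trial absent from the trial table."""


class EmptyInputError(VsddError):
    """An input file contains no data rows."""


class ParameterError(VsddError):
    """An operation was called with invalid parameters."""


class InsufficientDataError(VsddError):
    """Too few usable observations for the requested analysis."""


class UndefinedIndifferenceError(VsddError):
    """Indifference value is undefined because the value slope is zero."""
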