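"""Exception hierarchy.

Every error the library raises derives from :class:`WdsqiError`, so callers
(and the CLI, which maps them to exit code 2) can catch one base class.
"""


class WdsqiError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(WdsqiError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(WdsqiError):
    """Values violate a domain invariant (duplicates, NaN, out-of-range)."""


class ParameterError(WdsqiError):
    """A function parameter set violates its ordering constraints."""


class ConfigurationError(WdsqiError):
    """A configuration value is out of range or inconsistent with the data."""


class DegenerateInputError(WdsqiError):
    """Input is structurally valid but degenerate (e.g. zero-variance column)."""


class FixtureLookupError(WdsqiError, KeyError):
    """Unknown packaged-table identifier."""
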