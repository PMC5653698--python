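"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: :class:`SchemaError` -> 2,
:class:`ConfigurationError` -> 3, anything else -> 1.
"""


class SipError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SipError, ValueError):
    """An input file violates its documented schema (bad column, value, row)."""


class ConfigurationError(SipError, ValueError):
    """Inconsistent configuration: unknown enzyme, missing condition, bad key."""


class DegenerateInputError(SipError, ValueError):
    """An operation received input for which its result is undefined
    (e.g. normalizing an all-zero copy-number series)."""


class PairingError(SipError, ValueError):
    """Two density grids share no comparable fractions."""


class NotReachedError(SipError, ValueError):
    """A degradation series never reaches the requested degraded fraction."""
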