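"""Exception hierarchy shared across the package."""


class OvithermError(Exception):
    """Base class for all package errors."""


class SchemaError(OvithermError):
    """A CSV file does not match the documented column schema."""


class ValidationError(OvithermError):
    """A record violates a domain invariant."""


class ParameterError(OvithermError, ValueError):
    """An operation was called with invalid parameters."""


class FitError(OvithermError):
    """A statistical fit could not be performed or did not converge."""


class RangeError(OvithermError):
    """A date or value falls outside the span of the available data."""


class WindowError(OvithermError):
    """The oviposition window cannot be determined from the field records."""
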