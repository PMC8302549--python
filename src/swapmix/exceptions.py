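"""Exception hierarchy.

``SwapmixError`` is the base; the CLI maps validation-type errors to exit
code 1 and everything else to exit code 2.
"""


class SwapmixError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SwapmixError, ValueError):
    """A function argument is outside its documented domain."""


class EmptyInputError(SwapmixError, ValueError):
    """An operation that requires data received an empty collection."""


class ConfigurationError(SwapmixError):
    """A configuration value is infeasible or inconsistent."""


class SchemaError(SwapmixError):
    """A trial table is missing required columns or has the wrong types."""


class ValidationError(SwapmixError):
    """Trial data violate the experiment's structural invariants."""
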