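"""Exception hierarchy shared across the pipeline stages."""


class ThemeclustError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ThemeclustError):
    """A configuration value is invalid; the message names the offending field."""


class ValidationError(ThemeclustError):
    """An input value or data structure violates a precondition."""


class SchemaError(ValidationError):
    """A table is missing declared columns; the message lists the absences."""


class IntegrityError(ThemeclustError):
    """Packaged reference data failed its internal consistency checks."""


class DegenerateInputError(ValidationError):
    """A statistical routine received an input it is undefined on (e.g. a constant sample)."""
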