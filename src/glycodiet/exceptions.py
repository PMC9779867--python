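"""Exception hierarchy for glycodiet."""


class GlycoDietError(Exception):
    """Base class for all package errors."""


class SchemaError(GlycoDietError):
    """Input table does not match the expected column schema."""


class ValidationError(GlycoDietError):
    """Input values violate a domain invariant (range, level, closure)."""


class ConfigurationError(GlycoDietError):
    """A configuration object or definition table is internally inconsistent."""


class FitError(GlycoDietError):
    """A statistical fit could not be carried out on the given data."""
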