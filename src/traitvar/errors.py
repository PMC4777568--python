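"""Exception hierarchy for traitvar."""


class TraitVarError(Exception):
    """Base class for all traitvar errors."""


class ConfigurationError(TraitVarError, ValueError):
    """An invalid field in a synthetic-data configuration; names the field."""


class GenerationError(TraitVarError, RuntimeError):
    """Community assembly could not satisfy the configured constraints."""


class TableValidationError(TraitVarError, ValueError):
    """An individual-level trait table violates its schema."""


class EstimationError(TraitVarError, RuntimeError):
    """A variance-component or regression fit failed or is undefined."""
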