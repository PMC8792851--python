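"""Exception hierarchy for elderhealth."""


class ElderHealthError(Exception):
    """Base class for all package errors."""


class ValidationError(ElderHealthError):
    """Raised when an input object violates a structural invariant."""


class SchemaError(ValidationError):
    """Raised when a file does not conform to its declared schema."""


class EstimationError(ElderHealthError):
    """Raised when a model cannot be fitted on the data provided."""
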