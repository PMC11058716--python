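"""Exception hierarchy shared by all pipeline stages."""


class ProtGRNError(Exception):
    """Base class for all package errors."""


class ValidationError(ProtGRNError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A delimited file does not match the expected column layout."""


class SimulationError(ProtGRNError):
    """The synthetic dynamics diverged (overflow guard tripped)."""


class TuningError(ProtGRNError):
    """Hyperparameter search produced no usable score."""


class PipelineError(ProtGRNError):
    """A stage-level failure, e.g. an empty DE selection even on nominal p-values."""
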