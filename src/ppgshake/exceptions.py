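"""Exception hierarchy for ppgshake."""


class PPGShakeError(Exception):
    """Base class for all package errors."""


class SchemaError(PPGShakeError):
    """A file or table does not match the expected column schema."""


class DataError(PPGShakeError):
    """Input data violate a contract (non-monotone time, NaN samples, too short...)."""


class ParameterError(PPGShakeError):
    """A parameter is outside its admissible range."""


class PipelineError(PPGShakeError):
    """A study-pipeline stage failed; message carries stage and subject."""
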