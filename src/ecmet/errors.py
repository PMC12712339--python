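"""Exception hierarchy shared across the pipeline."""


class EcmetError(Exception):
    """Base class for all package errors."""


class FormatError(EcmetError):
    """A file failed strict validation; message carries file and line context."""


class ConfigurationError(EcmetError):
    """An invalid parameter or simulation/pipeline configuration."""


class ValidationError(EcmetError):
    """In-memory data violated a structural invariant."""
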