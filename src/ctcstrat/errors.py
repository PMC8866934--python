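"""Exception hierarchy shared across the pipeline stages."""


class CtcstratError(Exception):
    """Base class for all package errors."""


class SchemaError(CtcstratError):
    """An input table is missing required columns."""


class TableParseError(CtcstratError):
    """A value in an input table could not be parsed; carries the row number."""


class ValidationError(CtcstratError):
    """A record violates a domain invariant (e.g. circularity > 1)."""


class ConfigError(CtcstratError):
    """An invalid simulation or pipeline configuration."""


class AnalysisError(CtcstratError):
    """A statistical precondition is not met (e.g. a target level with < 2 patients)."""
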