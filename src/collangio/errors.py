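"""Exception types shared across the pipeline."""


class CollangioError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CollangioError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(CollangioError):
    """Input data violates a declared invariant."""


class ScoringError(CollangioError):
    """A gene set cannot be scored on the given matrix."""


class UndefinedStatisticError(CollangioError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
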