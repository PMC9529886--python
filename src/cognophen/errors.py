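"""Named exception types raised across the pipeline."""


class CognophenError(Exception):
    """Base class for all package errors."""


class ConfigError(CognophenError, ValueError):
    """Invalid simulation or analysis configuration."""


class PolicyError(ConfigError):
    """Unknown behavioral policy name."""


class DataError(CognophenError, ValueError):
    """Input data violate a precondition of an analysis step."""


class UnstableModelError(DataError):
    """Autoregressive model is unstable (spectral radius >= 1)."""
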