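"""Error taxonomy shared across the pipeline.

The CLI maps these onto process exit codes: configuration/parameter
problems -> 2, malformed or inconsistent data -> 3, numerical failures -> 4.
"""


class HelmstrainError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(HelmstrainError):
    """Invalid run configuration."""

    exit_code = 2


class ParameterError(ConfigError):
    """A function parameter is outside its valid domain."""

    exit_code = 2


class FormatError(HelmstrainError):
    """An input file does not conform to the expected layout."""

    exit_code = 3


class DataError(HelmstrainError):
    """Input data are structurally valid but inconsistent or unusable."""

    exit_code = 3


class NumericalError(HelmstrainError):
    """A numerical procedure failed (instability, degenerate values)."""

    exit_code = 4
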