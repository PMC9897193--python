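"""Exception hierarchy shared across the package.

CLI exit codes: ConfigError -> 2, DependencyError -> 3, ConditioningError -> 4.
"""


class TempobalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TempobalError, ValueError):
    """A configuration value violates the schema or an invariant."""


class InvalidFitnessError(ConfigError):
    """Rescaled (or raw) selection coefficient produces fitness >= 2 / s >= 1."""


class OverRescaledError(ConfigError):
    """Rescaling would push a diploid population size below 2."""


class ConditioningError(TempobalError, RuntimeError):
    """The focal allele failed to segregate at present within the attempt budget."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(
            f"focal allele not segregating at present after {attempts} attempts"
        )


class FormatError(TempobalError, ValueError):
    """Malformed ms-style haplotype file or metadata table."""


class InsufficientDataError(TempobalError, ValueError):
    """A class has too few samples to populate train/validation/test splits."""


class TrainingDivergedError(TempobalError, RuntimeError):
    """Loss became non-finite during optimisation."""


class DependencyError(TempobalError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
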