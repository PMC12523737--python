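"""Exception hierarchy.

Errors are grouped by pipeline stage so the command-line layer can map them
onto stable exit codes: configuration problems, input-data validation
problems, and computation failures.
"""


class HaariskError(Exception):
    """Base class for all package errors."""


class ConfigError(HaariskError):
    """Malformed or incomplete configuration."""


class DataValidationError(HaariskError):
    """Input table violates the schema or a domain invariant."""


class FormatError(DataValidationError):
    """Structural problem with a delimited-text input (missing column etc.)."""


class ComputationError(HaariskError):
    """A numerical operation cannot be carried out on the given inputs."""


class InsufficientDesignError(ComputationError):
    """Too few calibration levels, replicates or design runs."""


class DegenerateFitError(ComputationError):
    """A regression or scaling step has zero variance to work with."""


class DivisionDomainError(ComputationError):
    """A ratio-type figure of merit was requested with a zero denominator."""
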