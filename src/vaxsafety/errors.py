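"""Exception types raised across the pipeline.

Every validation failure is a named error so callers (and the study driver's
quarantine logic) can distinguish bad configuration from bad data.
"""


class VaxSafetyError(Exception):
    """Base class for all package errors."""


class ConfigValidationError(VaxSafetyError, ValueError):
    """A configuration value is missing, non-finite, or out of range."""


class TableParseError(VaxSafetyError, ValueError):
    """A delimited table violates the schema; carries file and line context."""

    def __init__(self, message: str, filename: str | None = None, line: int | None = None):
        self.filename = filename
        self.line = line
        where = ""
        if filename is not None:
            where = f" [{filename}" + (f", line {line}" if line is not None else "") + "]"
        super().__init__(message + where)


class UnknownBrandError(VaxSafetyError, ValueError):
    """A vaccine brand label is not in the known brand set."""


class UnknownOutcomeError(VaxSafetyError, KeyError):
    """An outcome name is not present in the outcome registry."""


class CohortError(VaxSafetyError, ValueError):
    """Cohort construction or covariate extraction received inconsistent inputs."""


class SingleArmError(VaxSafetyError, ValueError):
    """Propensity fitting requires observations in both arms."""


class EstimationError(VaxSafetyError, ValueError):
    """Rate or ratio estimation received degenerate inputs (e.g. zero person-time)."""


class CalibrationError(VaxSafetyError, ValueError):
    """Too few negative-control estimates to fit the empirical null."""


class MetaAnalysisError(VaxSafetyError, ValueError):
    """Meta-analysis received no estimable inputs."""
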