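"""Exception hierarchy for the pipeline."""


class AltishiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AltishiftError):
    """Invalid simulation or run configuration."""


class SchemaError(AltishiftError):
    """An input table does not match the documented schema."""


class NoCommonPointsError(AltishiftError):
    """No survey point was visited in both study periods."""


class UndefinedStatisticError(AltishiftError):
    """A derived statistic is undefined for the given input (e.g. zero total abundance)."""


class RankDeficiencyError(AltishiftError):
    """A model design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"design matrix is rank deficient in columns: {self.columns}")
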