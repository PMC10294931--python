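"""Exception types shared across the package."""


class AquariskError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AquariskError):
    """A model configuration document is malformed or fails validation."""


class MatrixError(AquariskError):
    """A pairwise comparison matrix violates its structural contract."""


class ConvergenceError(AquariskError):
    """The eigensolver failed to converge on a matrix."""


class ScoreSheetError(AquariskError):
    """A score sheet cannot be used for assessment.

    Carries the full validation report so callers can render diagnostics.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
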