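"""Exception and warning hierarchy for ctnorm.

All library errors derive from :class:`CtNormError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class CtNormError(Exception):
    """Base class for all ctnorm errors."""


class FormatError(CtNormError):
    """Input file does not match the expected layout or column set."""


class DuplicateRecordError(FormatError):
    """Duplicate (sample, gene) observations without a replicate column."""


class ConfigurationError(CtNormError):
    """Invalid configuration (missing reference genes, bad method name, ...)."""


class DegenerateDataError(CtNormError):
    """Data degenerate for the requested operation (zero variance, empty table)."""


class DegenerateRegressorError(DegenerateDataError):
    """Regressor has zero variance; a slope cannot be estimated."""


class InsufficientDataError(CtNormError):
    """Too few complete observations for the requested fit."""


class CollinearityError(CtNormError):
    """Reference genes are collinear; the multiple regression is rank deficient."""

    def __init__(self, message, offending_genes=()):
        super().__init__(message)
        self.offending_genes = list(offending_genes)


class OverfitError(InsufficientDataError):
    """No residual degrees of freedom left for a multiple regression."""


class AlignmentError(CtNormError):
    """Two dilution series cannot be matched point by point."""


class ParameterError(CtNormError):
    """A numeric parameter is outside its valid domain."""


class DesignError(CtNormError):
    """Group design is unusable (not exactly two groups, unknown samples, ...)."""


class PipelineError(CtNormError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class CtNormWarning(UserWarning):
    """Base warning class."""


class DegenerateFitWarning(CtNormWarning):
    """A regression had zero residual variance; p-value conventions applied."""


class FallbackWarning(CtNormWarning):
    """A per-gene fit failed or was gated out; fallback normalization applied."""


class SmallSampleWarning(CtNormWarning):
    """Sample size is small relative to the number of regressors."""


class InvalidAmplificationWarning(CtNormWarning):
    """Dilution regression slope is non-negative; efficiency undefined."""
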