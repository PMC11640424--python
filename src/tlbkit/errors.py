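"""Exception hierarchy for the thermogram-classification pipeline.

Every error raised on a user-facing code path derives from :class:`TlbError`
so callers can catch one type; subclasses mirror the failure domains
(file format, data validation, preprocessing coverage, model fitting, ...).
"""


class TlbError(Exception):
    """Base class for all tlbkit errors."""


class FormatError(TlbError):
    """A tabular input file does not have the expected columns or layout."""


class ValidationError(TlbError):
    """A thermogram or cohort violates a structural invariant."""


class DomainError(TlbError):
    """An operation was called with arguments outside its domain
    (e.g. a baseline window outside the measured temperature span)."""


class CoverageError(TlbError):
    """A thermogram does not span the temperature grid it must be
    interpolated onto."""


class NormalizationError(TlbError):
    """Area normalization is impossible (non-positive integral); typically
    signals a failed or pathological scan."""


class GridMismatchError(TlbError):
    """A requested temperature is absent from a feature grid, or a model was
    applied to features prepared on a different grid."""


class SelectionError(TlbError):
    """Top-scoring-pair selection cannot supply the requested number of
    pairs from the available grid."""


class FitError(TlbError):
    """Penalized logistic fitting is impossible (e.g. single-class input)."""


class SplitError(TlbError):
    """Train/validation partitioning by diagnosis confidence is impossible."""


class EvaluationError(TlbError):
    """A performance metric cannot be computed from the given scores."""


class GenerationError(TlbError):
    """A synthetic-cohort recipe is invalid."""


class PipelineError(TlbError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
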