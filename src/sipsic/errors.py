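"""Exception hierarchy for the sipsic package."""


class SipsicError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SipsicError):
    """A file does not conform to its declared format."""


class ConsistencyError(SipsicError):
    """Companion files disagree (e.g. MTX dimensions vs. id lists)."""


class ValidationError(SipsicError):
    """Data violates an invariant (negative values, duplicate names, NaN)."""


class ParameterError(SipsicError):
    """A parameter is outside its admissible range."""


class CoverageError(SipsicError):
    """A gene set has zero overlap with the expression matrix."""


class EmptyResultError(SipsicError):
    """An operation removed everything (all cells, all genes, all sets).

    May carry a ``report`` attribute describing what was filtered.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class AnalysisError(SipsicError):
    """A statistical or geometric analysis cannot proceed."""


class DegenerateVarianceError(AnalysisError):
    """Zero pooled variance with unequal means: the t statistic is undefined."""
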