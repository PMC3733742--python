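"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`SvplsError`, so callers can distinguish validation failures from
genuine bugs with a single ``except`` clause.
"""

from __future__ import annotations


class SvplsError(Exception):
    """Base class for all svpls errors."""


class DimensionMismatchError(SvplsError):
    """Shapes of matrix, design or scores are inconsistent."""


class DegenerateDesignError(SvplsError):
    """A variety has fewer than two samples; no residual df within the cell."""


class CollinearScoreError(SvplsError):
    """The shared design matrix is numerically rank deficient.

    ``column`` is the 0-based index of the offending design column
    (0 = intercept, 1 = variety indicator, 2.. = surrogate scores).
    """

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message)
        self.column = column


class ZeroRssError(SvplsError):
    """Residual sum of squares is zero: the fit is saturated, AIC/tests undefined."""


class NoVariationError(SvplsError):
    """Predictor matrix has (numerically) zero Frobenius norm; nothing to extract."""


class NoResidualVariationError(SvplsError):
    """ANOVA residuals are identically zero; no hidden structure to recover."""


class RankLimitError(SvplsError):
    """Requested more components than min(samples - 1, genes) permits."""


class NoSurrogatesError(SvplsError):
    """The selected model has no surrogate variables; hidden-effect display is empty."""


class UnknownIdError(SvplsError):
    """An identifier is not present in the fitted result."""

    def __init__(self, identifier: str):
        super().__init__(f"unknown identifier: {identifier!r}")
        self.identifier = identifier


class InvalidSpecError(SvplsError):
    """A simulation specification field violates its constraints."""

    def __init__(self, field: str, message: str):
        super().__init__(f"invalid simulation spec field {field!r}: {message}")
        self.field = field


class EmptyInputError(SvplsError):
    """An operation received an empty vector where at least one entry is required."""


class ParseError(SvplsError):
    """A delimited-text input could not be parsed; message carries coordinates."""


class MissingValueError(SvplsError):
    """An expression matrix contains an empty/NaN cell; message carries coordinates."""


class DuplicateIdError(SvplsError):
    """Gene or sample identifiers contain duplicates."""


class UsageError(SvplsError):
    """Invalid command-line invocation."""


class NonConvergenceWarning(UserWarning):
    """A NIPALS component hit max_iter before the score vector stabilised."""
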