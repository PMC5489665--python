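"""Exception hierarchy for the reference-gene pipeline.

Every user-facing failure mode has a distinct, named exception so callers
(and the CLI) can react to the cause rather than parse messages.
"""


class RgSelectError(Exception):
    """Base class for all rgselect errors."""


class TableValidationError(RgSelectError):
    """A table violates a structural invariant."""


class MissingTableError(RgSelectError, FileNotFoundError):
    """Input table file does not exist."""


class NonNumericCellError(TableValidationError):
    """A cell that must be numeric could not be parsed."""


class NegativeExpressionError(TableValidationError):
    """An expression value is negative (RPKM-like values must be >= 0)."""


class DuplicateGeneError(TableValidationError):
    """The same gene identifier appears more than once."""


class DuplicateSampleError(TableValidationError):
    """A (gene, sample) pair or sample metadata triple is duplicated."""


class UnknownColumnError(TableValidationError):
    """A long-format table has missing or unexpected columns."""


class ZeroMeanError(RgSelectError):
    """Relative expression / CV undefined because the mean is zero."""


class InsufficientDataError(RgSelectError):
    """Too few observations for the requested statistic."""


class InsufficientGenesError(RgSelectError):
    """Too few genes for the requested multi-gene statistic."""


class GroupSizeError(RgSelectError):
    """A sample group is too small for variance estimation."""


class MissingCtError(RgSelectError):
    """Missing Ct values where a complete matrix is required.

    Collapse technical replicates, impute, or drop the offending genes
    before calling geNorm/NormFinder.
    """


class AllMissingError(InsufficientDataError):
    """Every value in a Ct vector is missing."""


class DegenerateDesignError(RgSelectError):
    """Regression design is degenerate (e.g. all dilutions equal)."""


class ZeroVarianceError(RgSelectError):
    """Correlation undefined because one series has zero variance."""


class ConfigError(RgSelectError):
    """Invalid run configuration."""
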