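"""Exception hierarchy for bedbench.

All library errors derive from :class:`BedbenchError` so callers can catch
one base class; the CLI maps validation-type errors to exit code 2 and
numerical failures to exit code 3.
"""


class BedbenchError(Exception):
    """Base class for all bedbench errors."""


class SchemaError(BedbenchError):
    """A required column is missing or a column mapping is invalid."""


class ValidationError(BedbenchError):
    """An input value violates a domain invariant (names the offending unit)."""


class FixtureLookupError(BedbenchError, KeyError):
    """Unknown packaged-fixture name."""


class DegenerateDispersionError(BedbenchError):
    """A vector with zero dispersion cannot be z-standardized."""


class AlignmentError(BedbenchError):
    """Vectors that must be aligned have mismatched lengths or indexes."""


class DomainError(BedbenchError):
    """A value is outside the mathematical domain of a transform (e.g. 1/y with y <= 0)."""


class NonPhysicalIntervalError(DomainError):
    """A transformed-scale interval bound is non-positive, so its reciprocal is undefined."""


class SingularDesignError(BedbenchError):
    """The design matrix is rank deficient under the given weights."""

    def __init__(self, message, collinear_columns=()):
        super().__init__(message)
        self.collinear_columns = tuple(collinear_columns)


class UndefinedStatisticError(BedbenchError):
    """A fit statistic is undefined (e.g. R-squared with zero outcome variance)."""


class GeneratorError(BedbenchError):
    """The synthetic-data generator could not produce a valid table."""


class ExperimentError(BedbenchError):
    """A simulation experiment failed (e.g. too many singular replicates)."""
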