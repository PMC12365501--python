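"""Typed exceptions raised across the package.

Every error a caller may want to catch programmatically has its own class;
all inherit from :class:`TmtdiffError`.
"""


class TmtdiffError(Exception):
    """Base class for all tmtdiff errors."""


# --- data / IO ---------------------------------------------------------------

class MissingColumnError(TmtdiffError):
    """A required column is absent from an input table."""


class NonNumericIntensityError(TmtdiffError):
    """An intensity cell could not be parsed as a number."""


class DuplicateCellError(TmtdiffError):
    """Two rows map to the same (spectrum, run, channel) cell."""


class DuplicateSampleError(TmtdiffError):
    """A (run, channel) pair occurs more than once in the annotation."""


class MissingRequiredError(TmtdiffError):
    """A required annotation column is missing."""


class UnannotatedSampleError(TmtdiffError):
    """An assay column has no matching annotation row."""


# --- preprocessing -----------------------------------------------------------

class NonPositiveIntensityError(TmtdiffError):
    """A non-positive raw intensity was observed where log2 is required."""


class EmptyColumnError(TmtdiffError):
    """A sample column holds no observed values."""


class NoReferenceInRunError(TmtdiffError):
    """A run has no reference channel but reference normalization was asked."""


class NoStableBackgroundError(TmtdiffError):
    """No background feature survives filtering in a run."""


# --- summarization -----------------------------------------------------------

class AllMissingError(TmtdiffError):
    """A matrix holds no observed value at all."""


# --- model fitting -----------------------------------------------------------

class UnknownTermError(TmtdiffError):
    """A model term references a column that does not exist."""


class NoObservationsError(TmtdiffError):
    """No observations are available to build a design."""


class SingularFitError(TmtdiffError):
    """The mixed-model equations could not be solved."""


class IrreducibleModelError(TmtdiffError):
    """No identifiable sub-model exists for the requested fit."""


# --- inference ---------------------------------------------------------------

class InsufficientProteinsError(TmtdiffError):
    """Too few proteins to estimate the variance prior."""


class UnknownCoefficientError(TmtdiffError):
    """A contrast names a coefficient absent from every fit."""


# --- simulation / benchmarking ----------------------------------------------

class InvalidDesignError(TmtdiffError):
    """A simulation design violates its invariants."""


class StratumTooSmallError(TmtdiffError):
    """A permutation stratum holds fewer than two samples."""


class NoPositivesError(TmtdiffError):
    """TPR is undefined when there are no truth positives."""


class UnknownProteinError(TmtdiffError):
    """A result row references a protein absent from the ground truth."""
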