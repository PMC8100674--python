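"""Exception hierarchy for mmckit.

Every stage raises a subclass of :class:`MmcKitError` so pipeline callers can
distinguish data problems (bad input rows, impossible genotypes) from
programming errors.
"""


class MmcKitError(Exception):
    """Base class for all mmckit errors."""


class NoSharedAlleleError(MmcKitError):
    """Mother and child share no allele group at a locus.

    Signals a genotyping inconsistency or non-maternity; the pair cannot be
    used for inheritance-based marker selection at that locus.
    """


class NegativeMassError(MmcKitError):
    """A DNA mass below zero was supplied."""


class DegenerateCurveError(MmcKitError):
    """Standard-curve fit attempted on a single distinct input quantity."""


class EmptyPlateError(MmcKitError):
    """Replicate aggregation called with no wells."""


class NoCompartmentError(MmcKitError):
    """A chimerism profile was requested with no tested compartment."""


class OutOfWindowError(MmcKitError):
    """Gestational day outside the range of the median table."""


class NonPositiveError(MmcKitError):
    """A strictly positive quantity (analyte concentration, median) was <= 0."""


class ZeroDenominatorError(MmcKitError):
    """Subset percentage requested with zero total (CD45) events."""


class EmptyGroupError(MmcKitError):
    """Group comparison attempted with an empty group."""


class EmptySampleError(MmcKitError):
    """A rank test received an empty sample."""


class ZeroMarginError(MmcKitError):
    """A contingency-table margin is zero, so expected counts are undefined."""


class EnumerationCapError(MmcKitError):
    """Exact-test enumeration refused: table total exceeds the configured cap."""


class InsufficientPairsError(MmcKitError):
    """Correlation requested with fewer than three pairs."""


class MissingColumnError(MmcKitError):
    """A required column is absent from an input table."""


class FrequencyError(MmcKitError):
    """An allele-frequency table does not sum to one."""
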