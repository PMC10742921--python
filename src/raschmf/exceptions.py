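"""Exception hierarchy for calibration, scoring and equating failures."""


class RaschMFError(Exception):
    """Base class for all package errors."""


class DimensionMismatchError(RaschMFError, ValueError):
    """Vectors or matrices with incompatible dimensionality."""


class UnderdeterminedError(RaschMFError, ValueError):
    """Fewer observed values than coordinates to solve for."""


class DegenerateSpaceError(RaschMFError, ValueError):
    """Rank-deficient coordinate matrix: the spanned space has collapsed."""


class DegenerateColumnError(RaschMFError, ValueError):
    """A data column with zero variance or no usable observations."""


class MetricViolationError(RaschMFError, ValueError):
    """Raw values that do not conform to the declared column metric."""


class UncalibratedMetricError(RaschMFError, ValueError):
    """Inverse transform requested before the metric parameters were fitted."""


class InfeasibleHoldoutError(RaschMFError, ValueError):
    """Cannot hide the requested fraction of cells without starving a row/column."""


class InfeasibleSplitError(RaschMFError, ValueError):
    """An item half with too few columns to support the requested dimensionality."""


class UnknownAnchorError(RaschMFError, KeyError):
    """Anchor ids that are not present in the data."""


class InsufficientDataError(RaschMFError, ValueError):
    """Too few matched responses to score a person."""


class AssemblyError(RaschMFError, ValueError):
    """Inconsistent component dimensionalities when assembling an item bank."""


class EquatingError(RaschMFError, ValueError):
    """Common-item link is under-identified or absent."""
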