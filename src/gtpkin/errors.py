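"""Exception hierarchy shared by all gtpkin modules."""


class GtpkinError(Exception):
    """Base class for all gtpkin errors."""


class InvalidInputError(GtpkinError, ValueError):
    """Malformed or out-of-contract input (bad time grid, missing columns, ...)."""


class DegenerateFitError(GtpkinError):
    """Trace carries no usable signal (range below the noise floor)."""


class InsufficientControlsError(GtpkinError):
    """Fewer than the required number of usable vehicle-control wells."""


class ZeroVarianceError(GtpkinError):
    """Control wells have zero spread; z-distances are undefined."""


class ComparisonUndefinedError(GtpkinError):
    """Rate comparison requested with zero/missing standard errors."""


class DivisionUnstableError(GtpkinError):
    """Fold change requested against a rate pinned to the lower bound."""


class EmptySeriesError(GtpkinError):
    """All readings of a dual-channel series were dropped."""
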