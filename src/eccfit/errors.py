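"""Exception hierarchy for eccfit."""


class EccfitError(Exception):
    """Base class for all eccfit errors."""


class NotAnEllipseError(EccfitError):
    """A conic is not a real, non-degenerate ellipse."""


class DegenerateInputError(EccfitError):
    """Input data cannot support the requested operation (collinear, empty, ...)."""


class TooFewPointsError(DegenerateInputError):
    """Fewer points than the minimum a fitter requires."""


class OrderingError(EccfitError):
    """Points are not ordered by angle as the resampler requires."""


class NoAxisEstimateError(EccfitError):
    """Every fit underlying an axis estimate failed."""
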