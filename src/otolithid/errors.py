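"""Exception hierarchy for the otolith identification pipeline.

Every stage raises a subclass of :class:`OtolithError` so callers (and the
CLI) can distinguish a bad input image from a programming error.
"""


class OtolithError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(OtolithError, ValueError):
    """An input value violates a precondition (non-finite pixels, bad shapes...)."""


class NoObjectError(OtolithError):
    """The binary mask contains no foreground object after preprocessing."""


class DegenerateShapeError(OtolithError):
    """The segmented shape cannot yield a valid radius signal
    (e.g. the centroid coincides with a boundary pixel, or the boundary is
    shorter than 4 pixels)."""


class UnsupportedWindowError(OtolithError, ValueError):
    """The requested window function kind is not one of the supported 16."""


class DegenerateSpectrumError(OtolithError):
    """A spectrogram segment has zero-variance magnitudes or phases, so
    z-scores are undefined (pathological input such as an all-zero signal)."""


class SingularCovarianceError(OtolithError):
    """The pooled within-class covariance is numerically singular."""


class InsufficientDataError(OtolithError, ValueError):
    """A class has too few samples to estimate its statistics."""


class UnknownClassError(OtolithError, KeyError):
    """A test label was never seen during training."""


class InvalidSpecError(OtolithError, ValueError):
    """A synthetic species specification violates its constraints."""


class InvalidGeometryError(OtolithError, ValueError):
    """A synthetic shape does not fit on the requested canvas."""


class InvalidSplitError(OtolithError, ValueError):
    """Train/test specimen counts overlap or exceed the available specimens."""
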