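"""Exception hierarchy for colocpcc.

All errors raised by the library derive from :class:`ColocError` so callers
can catch the whole family with a single ``except`` clause.
"""


class ColocError(Exception):
    """Base class for all colocpcc errors."""


class ShapeMismatchError(ColocError):
    """The two channels (or two files) do not share the same shape."""


class InvalidInputError(ColocError):
    """An argument violates a precondition (negative threshold, bad count...)."""


class EmptySelectionError(ColocError):
    """The pixel-selection predicate admitted no pixels."""


class DegenerateSelectionError(ColocError):
    """The selected pixel set cannot support a correlation.

    Raised when fewer than two pixels are selected, or when exactly one of
    the two channels has zero variance over the selection (0/0 with no
    defensible convention).
    """


class NoContrastError(ColocError):
    """A constant image was passed to a histogram thresholding method."""


class InvalidSpecError(ColocError):
    """A synthetic-image specification is geometrically impossible."""


class PlacementError(ColocError):
    """The spot placement rule could not satisfy the separation constraint."""


class RegressionDegenerateError(ColocError):
    """The regressor channel has zero variance over the fit set."""


class ImageIOError(ColocError):
    """A TIFF file could not be read or the channels are inconsistent."""
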