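"""Exception hierarchy for the tipkinetics pipeline.

Every stage raises a dedicated subclass of :class:`TipKineticsError` so callers
can distinguish a bad parameter from a degenerate image or a failed fit.
"""


class TipKineticsError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(TipKineticsError, ValueError):
    """An input parameter violates a documented invariant."""


class SegmentationError(TipKineticsError):
    """A frame could not be segmented (constant image, empty foreground)."""


class TrajectoryError(TipKineticsError):
    """The centerline trajectory could not be extracted (e.g. cyclic skeleton)."""


class TipLocationError(TipKineticsError):
    """No trajectory point intersects the frame mask."""


class ProfileError(TipKineticsError):
    """An intensity profile could not be sampled (window leaves the image)."""


class FitError(TipKineticsError):
    """A nonlinear curve fit failed to converge or hit its bounds."""


class CorrelationError(TipKineticsError):
    """A correlation is undefined (zero variance, mismatched lag grids)."""


class PeakError(TipKineticsError):
    """No local maximum exists in the searched lag range."""


class RoiError(TipKineticsError):
    """A region of interest is empty or the tube is too short to build it."""
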