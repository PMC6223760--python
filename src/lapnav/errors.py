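"""Exception hierarchy for lapnav.

All errors derive from :class:`LapnavError` so callers can catch the
package's failures with a single except clause.
"""


class LapnavError(Exception):
    """Base class for all lapnav errors."""


class DegenerateAxesError(LapnavError, ValueError):
    """Frame construction axes are (anti)parallel or zero."""


class EmptyInputError(LapnavError, ValueError):
    """An operation requiring at least one sample received none."""


class MethodMismatchError(LapnavError, ValueError):
    """A registration result of the wrong method was passed."""


class InsufficientPointsError(LapnavError, ValueError):
    """Fewer landmark pairs than the registration method requires."""


class DegenerateConfigurationError(LapnavError, ValueError):
    """Point configuration is (near-)collinear; the fit is ill-posed."""


class InsufficientMotionError(LapnavError, ValueError):
    """Pivot-calibration poses do not span enough orientations."""


class OutOfBoundsError(LapnavError, ValueError):
    """A pixel coordinate lies outside the ultrasound image grid."""


class UnknownAxisError(LapnavError, ValueError):
    """Displacement axis is neither 'frontal' nor 'longitudinal'."""


class EmptyGroupError(LapnavError, ValueError):
    """A summary group holds fewer than two trials."""


class DegenerateError(LapnavError, ValueError):
    """A statistical test received data with zero within-variance."""
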