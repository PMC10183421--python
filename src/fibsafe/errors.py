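"""Exception hierarchy for fibsafe."""


class FibsafeError(Exception):
    """Base class for all fibsafe errors."""


class ParameterError(FibsafeError, ValueError):
    """Invalid or inconsistent parameter combination."""


class DegenerateContourError(FibsafeError):
    """Contour is self-intersecting, too small, or has zero-length features."""


class LandmarkMismatchError(FibsafeError):
    """A landmark violates its placement contract (e.g. apex off the contour)."""


class LocationOffCortexError(FibsafeError):
    """A queried point does not lie on either lateral cortical edge."""


class NoLateralExitError(FibsafeError):
    """An axis does not exit through the lateral fibular cortex."""


class InfeasibleTunnelError(FibsafeError):
    """No axis orientation admits a drill of the requested diameter."""


class DetectionFailureError(FibsafeError):
    """Automatic apex detection found too few corner candidates."""


class DegenerateConfigurationError(FibsafeError):
    """Landmark configuration is collinear or otherwise unusable for registration."""


class UndefinedStatisticError(FibsafeError):
    """A statistic is undefined for the given input (e.g. sd of a single value)."""


class PipelineError(FibsafeError):
    """A pipeline stage failed for every subject."""
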