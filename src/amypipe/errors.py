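"""Exception hierarchy for amypipe."""


class AmypipeError(Exception):
    """Base class for all amypipe errors."""


class DimensionalityError(AmypipeError):
    """Volume payload is not 3-D (or otherwise has the wrong rank)."""


class FormatError(AmypipeError):
    """File content violates the expected on-disk format (e.g. singular affine)."""


class ParameterError(AmypipeError):
    """A user-supplied parameter is out of its valid range."""


class EmptyWindowError(AmypipeError):
    """No dynamic frame overlaps the requested averaging window."""


class GeometryError(AmypipeError):
    """Requested grid cannot contain the phantom anatomy."""


class ConvergenceError(AmypipeError):
    """An iterative optimiser failed to converge."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class EstimationError(AmypipeError):
    """Warp or mixture estimation failed irrecoverably."""


class VOIError(AmypipeError):
    """A volume of interest is empty or unusable."""


class ReferenceError_(AmypipeError):
    """Reference-region statistic is non-positive."""


class UsageError(AmypipeError):
    """Operation called with incompatible objects (e.g. wrong warp direction)."""


class CoverageError(AmypipeError):
    """Required pipeline rows are missing for some subjects."""
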