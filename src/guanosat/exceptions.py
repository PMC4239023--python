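"""Exception hierarchy.

Every error raised on a bad input or a degenerate fit derives from
:class:`GuanosatError`, so callers can catch the package's failures
without swallowing programming errors.
"""


class GuanosatError(Exception):
    """Base class for all package errors."""


class ParameterError(GuanosatError, ValueError):
    """A numeric parameter is outside its admissible range."""


class GeometryError(GuanosatError, ValueError):
    """A colony footprint does not fit inside the scene raster."""


class SchemaError(GuanosatError, ValueError):
    """A file or array does not conform to the declared schema."""


class InsufficientDataError(GuanosatError, ValueError):
    """Too few observations to fit the requested model."""


class DegenerateTrainingError(GuanosatError, ValueError):
    """Training covariance is singular even after regularization."""


class SeparationError(GuanosatError, ValueError):
    """Logistic fit is degenerate (one outcome class, or complete separation)."""


class NoMissingMassError(GuanosatError, ValueError):
    """Detection is effectively certain everywhere; E[N | missed] is undefined."""
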