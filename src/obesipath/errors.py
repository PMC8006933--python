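"""Exception hierarchy shared across the pipeline.

Every error raised by obesipath derives from :class:`ObesipathError`, so
callers (and the CLI) can catch pipeline failures without masking genuine
programming errors.
"""


class ObesipathError(Exception):
    """Base class for all obesipath errors."""


class InvalidMeasurementError(ObesipathError, ValueError):
    """Non-positive weight, height or BMI."""


class InvalidFigureError(ObesipathError, ValueError):
    """Silhouette figure outside the 1-9 rating scale."""


class InvalidResponseError(ObesipathError, ValueError):
    """Likert response outside the admissible set."""


class ShapeError(ObesipathError, ValueError):
    """Input with the wrong length / dimensions."""


class InvalidProbabilityError(ObesipathError, ValueError):
    """Probability outside [0, 1]."""


class InvalidParameterError(ObesipathError, ValueError):
    """Preference parameter outside its admissible domain."""


class MultipleSwitchError(ObesipathError, ValueError):
    """Non-monotone choice vector: more than one A->B switch in a series."""


class InconsistencyError(ObesipathError, ValueError):
    """Switch-point combination admits no preference parameters."""


class DegenerateVariableError(ObesipathError, ValueError):
    """Zero-variance column where variation is required."""


class ModelSpecificationError(ObesipathError, ValueError):
    """Path model refers to missing variables or has no endogenous variable."""


class CollinearityError(ObesipathError, ValueError):
    """Perfectly (or numerically) collinear predictor block."""


class ConfigError(ObesipathError, ValueError):
    """Invalid simulation or run configuration."""
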