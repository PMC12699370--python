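"""Exception hierarchy.

``ConfigError``-derived errors map to CLI exit code 2, everything else
(data problems) to exit code 1.
"""


class CytocurvError(Exception):
    """Base class for all package errors."""


class ConfigError(CytocurvError):
    """Invalid configuration: unknown keys, bad parameter values."""


class ParameterError(ConfigError, ValueError):
    """A numeric parameter is out of its valid domain."""


class DataError(CytocurvError):
    """Input data cannot be analyzed."""


class DegenerateContourError(DataError, ValueError):
    """Fewer than three distinct points, or otherwise no usable outline."""


class SegmentationError(DataError, RuntimeError):
    """No foreground could be segmented from the image."""


class GenerationError(CytocurvError, ValueError):
    """A synthetic-data spec yields an invalid (e.g. non-simple) object."""
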