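"""Exception hierarchy for rgbdclean.

Every error raised by the library derives from :class:`RgbdCleanError`, so
callers can catch one base class. Subclasses also derive from the closest
builtin (``ValueError`` for bad values, etc.) to stay idiomatic.
"""


class RgbdCleanError(Exception):
    """Base class for all rgbdclean errors."""


class InvalidDepthError(RgbdCleanError, ValueError):
    """A depth value was zero or negative where a positive depth is required."""


class BehindCameraError(RgbdCleanError, ValueError):
    """A 3D point with non-positive Z cannot be projected through a pinhole."""


class DomainError(RgbdCleanError, ValueError):
    """An input value lies outside the documented domain (non-finite, out of range)."""


class ShapeError(RgbdCleanError, ValueError):
    """Array shapes of jointly-used inputs do not agree."""


class InvalidTransformError(RgbdCleanError, ValueError):
    """A rotation matrix is not a proper orthonormal rotation."""


class InvalidBoxError(RgbdCleanError, ValueError):
    """A 3D bounding box has inverted bounds."""


class EmptyHistogramError(RgbdCleanError, ValueError):
    """No valid pixels were available to build a gray-level histogram."""


class DegenerateHistogramError(RgbdCleanError, ValueError):
    """All histogram mass sits at a single gray level; no threshold exists."""


class InsufficientPointsError(RgbdCleanError, ValueError):
    """The point cloud is too small for the requested neighborhood query."""


class SceneConfigError(RgbdCleanError, ValueError):
    """A synthetic-scene configuration is inconsistent or infeasible."""


class EvaluationError(RgbdCleanError, ValueError):
    """Ground-truth labels do not cover the evaluated points."""


class DegenerateSegmentationError(RgbdCleanError, RuntimeError):
    """The pipeline cannot segment the frame; carries the failing stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
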