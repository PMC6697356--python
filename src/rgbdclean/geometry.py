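"""Pinhole camera geometry for a two-sensor RGB-D rig.

An RGB-D camera carries two sensors — an infrared depth sensor and an RGB
sensor — each with its own pinhole intrinsics, related by a rigid extrinsic
transform. This module provides the three primitives the alignment pipeline
composes: deprojection of a depth pixel to a 3D point, rigid transformation
between sensor frames, and projection of a 3D point into a pixel.

Conventions
-----------
* Pixel coordinates are 0-based and continuous: integer ``(u, v)`` is the ray
  through the *center* of that pixel, ``u`` indexes columns, ``v`` rows.
* Depths and translations are in meters.
* ``fx, fy`` are focal lengths in pixel units (focal length divided by the
  physical pixel pitch along each axis); ``cx, cy`` is the principal point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BehindCameraError,
    DomainError,
    InvalidDepthError,
    InvalidTransformError,
)

__all__ = [
    "CameraIntrinsics",
    "RigidTransform",
    "deproject_depth_pixel",
    "project_point",
    "transform_point",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters of one sensor.

    Attributes
    ----------
    fx, fy : float
        Focal lengths in pixel units along u (columns) and v (rows).
    cx, cy : float
        Principal point in pixels.
    width, height : int
        Sensor resolution in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise DomainError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if self.width < 1 or self.height < 1:
            raise DomainError(f"image size must be >= 1, got {self.width}x{self.height}")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise DomainError(
                f"principal point ({self.cx}, {self.cy}) outside image {self.width}x{self.height}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) — numpy array ordering."""
        return (self.height, self.width)


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` between sensor frames.

    ``R`` must be orthonormal with determinant +1 (checked to 1e-9 at
    construction); ``t`` is in meters.
    """

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidTransformError(f"R must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise InvalidTransformError("R and t must be finite")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidTransformError("R is not orthonormal (R^T R != I to 1e-9)")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise InvalidTransformError("det(R) != +1 to 1e-9 (improper rotation)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an array of points with trailing dimension 3."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        Rinv = self.R.T
        return RigidTransform(Rinv, -Rinv @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)


def deproject_depth_pixel(u, v, z, K: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel ``(u, v)`` at depth ``z`` (meters) to a 3D point.

    Inverts the pinhole projection: ``X = (u - cx) z / fx``,
    ``Y = (v - cy) z / fy``, ``Z = z``. Coordinates need not be integral.

    Raises
    ------
    InvalidDepthError
        If ``z <= 0``.
    DomainError
        If any input is non-finite.
    """
    u = float(u)
    v = float(v)
    z = float(z)
    if not (np.isfinite(u) and np.isfinite(v) and np.isfinite(z)):
        raise DomainError("pixel coordinates and depth must be finite")
    if z <= 0:
        raise InvalidDepthError(f"depth must be positive, got z={z}")
    return np.array([(u - K.cx) * z / K.fx, (v - K.cy) * z / K.fy, z])


def project_point(p, K: CameraIntrinsics) -> tuple[float, float, float]:
    """Project a 3D point (meters) to continuous pixel coordinates.

    Returns ``(u, v, z)`` with ``u = fx X / Z + cx``, ``v = fy Y / Z + cy``.
    No rounding and no bounds clamping happen here; callers decide sampling.

    Raises
    ------
    BehindCameraError
        If ``Z <= 0``.
    """
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise DomainError("point coordinates must be finite")
    X, Y, Z = p
    if Z <= 0:
        raise BehindCameraError(f"point behind camera (Z={Z})")
    return (K.fx * X / Z + K.cx, K.fy * Y / Z + K.cy, Z)


def transform_point(p, T: RigidTransform) -> np.ndarray:
    """Apply the rigid motion ``R @ p + t`` to a single point."""
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise DomainError("point coordinates must be finite")
    return T.apply(p)
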