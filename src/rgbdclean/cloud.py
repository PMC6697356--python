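"""Point-cloud containers, bounding-box pre-filter and mask-based extraction.

The pipeline keeps the cloud *organized*: one (possibly invalid) 3D point per
depth pixel, preserving the grid topology. The bounding-box stage therefore
*zeroes* out-of-range points instead of deleting them, so the pixel-to-point
correspondence survives for the later mask-based extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidBoxError, ShapeError
from .images import ColorImage, MappingImage

__all__ = [
    "OrganizedPointCloud",
    "UnorganizedCloud",
    "BoundingBox3D",
    "ExtractionResult",
    "bbox_filter",
    "extract_by_mask",
]


@dataclass
class OrganizedPointCloud:
    """H x W grid of 3D points (meters) with validity and optional color.

    Invalid entries hold (0, 0, 0); colors, if present, share the grid shape.
    """

    points: np.ndarray
    valid: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        val = np.asarray(self.valid, dtype=bool)
        if pts.ndim != 3 or pts.shape[2] != 3:
            raise ShapeError(f"points must be H x W x 3, got {pts.shape}")
        if val.shape != pts.shape[:2]:
            raise ShapeError(f"valid shape {val.shape} != grid shape {pts.shape[:2]}")
        pts = pts.copy()
        pts[~val] = 0.0
        if self.colors is not None:
            col = np.asarray(self.colors)
            if col.shape[:2] != pts.shape[:2] or col.shape[2] != 3:
                raise ShapeError(f"colors shape {col.shape} incompatible with grid {pts.shape[:2]}")
            col = col.copy()
            col[~val] = 0
            self.colors = col
        self.points = pts
        self.valid = val

    @property
    def shape(self) -> tuple[int, int]:
        return self.points.shape[:2]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_unorganized(self) -> "UnorganizedCloud":
        """Flatten valid points to a list, remembering their pixel indices."""
        idx = np.flatnonzero(self.valid.ravel())
        pts = self.points.reshape(-1, 3)[idx]
        col = None if self.colors is None else self.colors.reshape(-1, 3)[idx]
        return UnorganizedCloud(points=pts, colors=col, pixel_index=idx)


@dataclass
class UnorganizedCloud:
    """Flat list of 3D points with optional colors and source pixel indices."""

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    pixel_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ShapeError("cloud coordinates must be finite")
        self.points = pts
        if self.colors is not None:
            self.colors = np.asarray(self.colors).reshape(-1, 3)
            if len(self.colors) != len(pts):
                raise ShapeError("colors length != points length")
        if self.pixel_index is not None:
            self.pixel_index = np.asarray(self.pixel_index, dtype=int).reshape(-1)
            if len(self.pixel_index) != len(pts):
                raise ShapeError("pixel_index length != points length")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned box in meters with closed bounds on every axis."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    zmin: float
    zmax: float

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax or self.zmin > self.zmax:
            raise InvalidBoxError(f"inverted bounds in {self}")

    @classmethod
    def unbounded(cls) -> "BoundingBox3D":
        """A box containing every finite point (pre-filter disabled)."""
        inf = math.inf
        return cls(-inf, inf, -inf, inf, -inf, inf)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized closed-inequality membership test on (..., 3) points."""
        p = np.asarray(points, dtype=float)
        return (
            (p[..., 0] >= self.xmin) & (p[..., 0] <= self.xmax)
            & (p[..., 1] >= self.ymin) & (p[..., 1] <= self.ymax)
            & (p[..., 2] >= self.zmin) & (p[..., 2] <= self.zmax)
        )


@dataclass
class ExtractionResult:
    """Partition of the valid cloud into target and removed point sets.

    ``target_index``/``removed_index`` are flat pixel indices into the source
    grid; the point/color arrays are aligned with them. The two index sets are
    disjoint and together cover every valid pixel of the input cloud.
    """

    target_points: np.ndarray
    target_colors: Optional[np.ndarray]
    target_index: np.ndarray
    removed_points: np.ndarray
    removed_colors: Optional[np.ndarray]
    removed_index: np.ndarray
    target_mask: np.ndarray

    @property
    def n_target(self) -> int:
        return len(self.target_index)

    @property
    def n_removed(self) -> int:
        return len(self.removed_index)


def bbox_filter(
    cloud: OrganizedPointCloud,
    mapping: Optional[MappingImage],
    box: BoundingBox3D,
) -> tuple[OrganizedPointCloud, Optional[MappingImage]]:
    """Zero every pixel whose point falls outside ``box`` on any axis.

    Out-of-range (or already invalid) pixels get point (0,0,0), color
    (0,0,0) and valid=False; in-range pixels pass through untouched. The grid
    shape is preserved — this is zeroing, not deletion — so downstream
    mask stages keep their pixel correspondence. Bounds are closed: a point
    exactly on a face is kept.
    """
    if mapping is not None and mapping.shape != cloud.shape:
        raise ShapeError(f"mapping shape {mapping.shape} != cloud shape {cloud.shape}")
    keep = cloud.valid & box.contains(cloud.points)
    colors = None if cloud.colors is None else cloud.colors
    out_cloud = OrganizedPointCloud(points=cloud.points, valid=keep, colors=colors)
    out_mapping = None
    if mapping is not None:
        vals = mapping.values.copy()
        vals[~keep] = 0
        out_mapping = MappingImage(
            color=ColorImage(vals, normalized=mapping.color.normalized),
            valid=mapping.valid & keep,
        )
    return out_cloud, out_mapping


def extract_by_mask(cloud: OrganizedPointCloud, mask: np.ndarray) -> ExtractionResult:
    """Split the valid points of ``cloud`` by a binary target mask.

    Valid pixels with mask 1 become the target cloud; valid pixels with mask
    0 become the removed cloud; invalid pixels contribute to neither. The
    result is an exact partition: ``n_target + n_removed == cloud.n_valid``.
    """
    mask = np.asarray(mask)
    if mask.shape != cloud.shape:
        raise ShapeError(f"mask shape {mask.shape} != cloud shape {cloud.shape}")
    flat_mask = mask.ravel().astype(bool)
    flat_valid = cloud.valid.ravel()
    pts = cloud.points.reshape(-1, 3)
    cols = None if cloud.colors is None else cloud.colors.reshape(-1, 3)

    target_idx = np.flatnonzero(flat_valid & flat_mask)
    removed_idx = np.flatnonzero(flat_valid & ~flat_mask)
    return ExtractionResult(
        target_points=pts[target_idx],
        target_colors=None if cols is None else cols[target_idx],
        target_index=target_idx,
        removed_points=pts[removed_idx],
        removed_colors=None if cols is None else cols[removed_idx],
        removed_index=removed_idx,
        target_mask=mask.astype(np.uint8),
    )
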