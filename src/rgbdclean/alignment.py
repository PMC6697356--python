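"""Color-to-depth alignment and organized-cloud construction.

For every depth pixel with a valid depth the alignment composes the three
geometric primitives: deproject the pixel into the depth sensor's 3D frame,
move the point into the color sensor's frame with the rig extrinsics, and
project it through the color sensor's pinhole. The color image is then
sampled at the resulting location, producing the *mapping image* — the color
image resampled onto the depth grid, so each depth pixel/point pair carries
an RGB value ("corresponding point pairs" of the two sensors).

Sampling is nearest-pixel with round-half-away-from-zero, chosen over
bilinear interpolation so that the mapping image contains only RGB values
actually present in the color image and downstream histograms are bit-exact
reproducible. Occlusion is not resolved: two depth pixels at different
depths may legitimately sample the same color pixel. Depth pixels whose
projection falls outside the color image are marked invalid rather than
clamped, since clamping would fabricate rim colors.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cloud import OrganizedPointCloud
from .errors import ShapeError
from .geometry import CameraIntrinsics, RigidTransform
from .images import ColorImage, DepthImage, MappingImage

__all__ = ["align_color_to_depth", "depth_to_cloud", "nearest_pixel"]


def nearest_pixel(x: np.ndarray) -> np.ndarray:
    """Round continuous pixel coordinates half away from zero, to int."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x).astype(np.int64)


def _deproject_grid(depth: DepthImage, K: CameraIntrinsics) -> np.ndarray:
    """Per-pixel back-projection of the whole grid (invalid pixels give z=0)."""
    h, w = depth.shape
    v, u = np.mgrid[0:h, 0:w].astype(float)
    z = depth.values
    return np.stack([(u - K.cx) * z / K.fx, (v - K.cy) * z / K.fy, z], axis=-1)


def align_color_to_depth(
    depth: DepthImage,
    color: ColorImage,
    K_depth: CameraIntrinsics,
    K_color: CameraIntrinsics,
    T_depth_to_color: RigidTransform,
) -> MappingImage:
    """Resample the color image onto the depth grid (the mapping image).

    Per depth pixel with z > 0: deproject with ``K_depth``, transform with
    ``T_depth_to_color``, project with ``K_color``, and sample the color
    image at the nearest pixel. Pixels with no depth, a behind-camera
    transform result, or an out-of-bounds projection become invalid and
    carry color (0, 0, 0).
    """
    if depth.shape != K_depth.shape:
        raise ShapeError(
            f"depth image shape {depth.shape} != depth intrinsics shape {K_depth.shape}"
        )
    if color.shape != K_color.shape:
        raise ShapeError(
            f"color image shape {color.shape} != color intrinsics shape {K_color.shape}"
        )
    pts = _deproject_grid(depth, K_depth)
    pts_c = T_depth_to_color.apply(pts)

    z2 = pts_c[..., 2]
    valid = depth.valid & (z2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u2 = K_color.fx * pts_c[..., 0] / z2 + K_color.cx
        v2 = K_color.fy * pts_c[..., 1] / z2 + K_color.cy
    ui = nearest_pixel(np.where(valid, u2, 0.0))
    vi = nearest_pixel(np.where(valid, v2, 0.0))
    inb = (ui >= 0) & (ui < K_color.width) & (vi >= 0) & (vi < K_color.height)
    valid &= inb

    out = np.zeros(depth.shape + (3,), dtype=color.values.dtype)
    out[valid] = color.values[vi[valid], ui[valid]]
    return MappingImage(color=ColorImage(out, normalized=color.normalized), valid=valid)


def depth_to_cloud(
    depth: DepthImage,
    K: CameraIntrinsics,
    colors: Optional[MappingImage] = None,
) -> OrganizedPointCloud:
    """Back-project every depth pixel into an organized point cloud.

    Grid topology is preserved: one point per pixel, invalid where depth is
    missing. When a mapping image is supplied its colors are carried onto
    the points (pixels whose mapping is invalid keep their geometry but get
    color (0, 0, 0)).
    """
    if depth.shape != K.shape:
        raise ShapeError(f"depth shape {depth.shape} != intrinsics shape {K.shape}")
    if colors is not None and colors.shape != depth.shape:
        raise ShapeError(f"mapping shape {colors.shape} != depth shape {depth.shape}")
    pts = _deproject_grid(depth, K)
    col = None if colors is None else colors.values
    return OrganizedPointCloud(points=pts, valid=depth.valid, colors=col)
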