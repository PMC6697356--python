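"""File I/O: PNG images, camera-config JSON, and ASCII PLY point clouds.

On-disk conventions:

* depth — 16-bit grayscale PNG, stored units converted to meters with the
  ``depth_scale`` from the camera config (default 0.001 m per unit);
* color — 8-bit RGB PNG;
* masks — 8-bit PNG with {0, 255};
* labels — 8-bit PNG holding the raw label codes (0..5);
* clouds — ASCII PLY with x, y, z float properties, uchar red/green/blue,
  and an optional int32 ``pixel_index`` tying each vertex back to its
  source depth pixel;
* camera config — JSON with ``depth``, ``color`` and ``extrinsics`` blocks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np

from .cloud import UnorganizedCloud
from .errors import DomainError
from .geometry import CameraIntrinsics, RigidTransform
from .images import ColorImage, DepthImage

__all__ = [
    "read_depth_png",
    "write_depth_png",
    "read_color_png",
    "write_color_png",
    "read_mask_png",
    "write_mask_png",
    "read_label_png",
    "write_label_png",
    "load_camera_config",
    "save_camera_config",
    "read_ply",
    "write_ply",
    "write_sigma_curve_csv",
]

PathLike = Union[str, Path]


# --- PNG ------------------------------------------------------------------

def write_depth_png(path: PathLike, depth: DepthImage) -> None:
    """Store depth as 16-bit PNG in ``depth_scale`` units (mm by default)."""
    units = np.round(depth.values / depth.depth_scale)
    if np.any(units > np.iinfo(np.uint16).max):
        raise DomainError("depth exceeds the 16-bit range at this depth_scale")
    iio.imwrite(Path(path), units.astype(np.uint16))


def read_depth_png(path: PathLike, depth_scale: float = 0.001) -> DepthImage:
    raw = iio.imread(Path(path))
    if raw.ndim != 2:
        raise DomainError(f"expected a single-channel depth PNG, got shape {raw.shape}")
    return DepthImage(raw.astype(float) * depth_scale, depth_scale=depth_scale)


def write_color_png(path: PathLike, color: ColorImage) -> None:
    vals = color.values
    if color.normalized:
        vals = np.floor(vals * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), vals)


def read_color_png(path: PathLike) -> ColorImage:
    raw = iio.imread(Path(path))
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[..., :3]
    return ColorImage(raw, normalized=False)


def write_mask_png(path: PathLike, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask_png(path: PathLike) -> np.ndarray:
    return (iio.imread(Path(path)) > 127).astype(np.uint8)


def write_label_png(path: PathLike, labels: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(labels).astype(np.uint8))


def read_label_png(path: PathLike) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.int64)


# --- camera config --------------------------------------------------------

def _intrinsics_to_dict(K: CameraIntrinsics) -> dict:
    return {"fx": K.fx, "fy": K.fy, "cx": K.cx, "cy": K.cy, "width": K.width, "height": K.height}


def _intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics(
        fx=float(d["fx"]), fy=float(d["fy"]), cx=float(d["cx"]), cy=float(d["cy"]),
        width=int(d["width"]), height=int(d["height"]),
    )


def save_camera_config(
    path: PathLike,
    K_depth: CameraIntrinsics,
    K_color: CameraIntrinsics,
    extrinsics: RigidTransform,
    depth_scale: float = 0.001,
) -> None:
    cfg = {
        "depth": {**_intrinsics_to_dict(K_depth), "depth_scale": depth_scale},
        "color": _intrinsics_to_dict(K_color),
        "extrinsics": {
            "R": [float(x) for x in extrinsics.R.ravel()],  # row-major
            "t": [float(x) for x in extrinsics.t],
        },
    }
    Path(path).write_text(json.dumps(cfg, indent=2))


def load_camera_config(
    path: PathLike,
) -> tuple[CameraIntrinsics, CameraIntrinsics, RigidTransform, float]:
    """Returns (K_depth, K_color, depth-to-color transform, depth_scale)."""
    cfg = json.loads(Path(path).read_text())
    K_depth = _intrinsics_from_dict(cfg["depth"])
    K_color = _intrinsics_from_dict(cfg["color"])
    R = np.asarray(cfg["extrinsics"]["R"], dtype=float).reshape(3, 3)
    t = np.asarray(cfg["extrinsics"]["t"], dtype=float)
    depth_scale = float(cfg["depth"].get("depth_scale", 0.001))
    return K_depth, K_color, RigidTransform(R, t), depth_scale


# --- ASCII PLY ------------------------------------------------------------

def write_ply(path: PathLike, cloud: UnorganizedCloud) -> None:
    """Write an ASCII PLY with x/y/z, optional RGB and optional pixel_index."""
    n = len(cloud)
    has_color = cloud.colors is not None
    has_index = cloud.pixel_index is not None
    lines = ["ply", "format ascii 1.0", f"element vertex {n}"]
    lines += ["property float x", "property float y", "property float z"]
    if has_color:
        lines += ["property uchar red", "property uchar green", "property uchar blue"]
    if has_index:
        lines += ["property int pixel_index"]
    lines += ["end_header"]

    cols: list[np.ndarray] = [cloud.points[:, i] for i in range(3)]
    fmt = ["%.6f"] * 3
    if has_color:
        rgb = np.asarray(cloud.colors)
        if rgb.dtype.kind == "f":
            rgb = np.floor(np.clip(rgb, 0, 1) * 255.0 + 0.5)
        cols += [rgb[:, i].astype(int) for i in range(3)]
        fmt += ["%d"] * 3
    if has_index:
        cols += [cloud.pixel_index.astype(int)]
        fmt += ["%d"]
    body = "\n".join(
        " ".join(f % c[i] for f, c in zip(fmt, cols)) for i in range(n)
    )
    Path(path).write_text("\n".join(lines) + ("\n" + body if n else "") + "\n")


def read_ply(path: PathLike) -> UnorganizedCloud:
    """Read an ASCII PLY written by :func:`write_ply` (or compatible)."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise DomainError(f"{path} is not a PLY file")
    props: list[str] = []
    n = 0
    i = 1
    while i < len(text):
        line = text[i].strip()
        i += 1
        if line == "end_header":
            break
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise DomainError("only ASCII PLY is supported")
        if parts[0] == "element" and parts[1] == "vertex":
            n = int(parts[2])
        elif parts[0] == "element":
            raise DomainError(f"unsupported PLY element {parts[1]!r}")
        elif parts[0] == "property":
            props.append(parts[-1])
    else:
        raise DomainError("PLY header has no end_header")

    rows = [text[i + j].split() for j in range(n)]
    data = np.asarray(rows, dtype=float) if n else np.zeros((0, len(props)))
    col = {name: k for k, name in enumerate(props)}
    for axis in ("x", "y", "z"):
        if axis not in col:
            raise DomainError(f"PLY is missing vertex property {axis!r}")
    pts = data[:, [col["x"], col["y"], col["z"]]]
    colors = None
    if all(c in col for c in ("red", "green", "blue")):
        colors = data[:, [col["red"], col["green"], col["blue"]]].astype(np.uint8)
    index = data[:, col["pixel_index"]].astype(int) if "pixel_index" in col else None
    return UnorganizedCloud(points=pts, colors=colors, pixel_index=index)


# --- misc -----------------------------------------------------------------

def write_sigma_curve_csv(path: PathLike, curve: np.ndarray) -> None:
    """Dump the between-class-variance curve as (k, sigma2) CSV rows."""
    lines = ["k,sigma2"] + [f"{k},{s:.12g}" for k, s in enumerate(np.asarray(curve))]
    Path(path).write_text("\n".join(lines) + "\n")
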