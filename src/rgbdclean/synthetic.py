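"""Labeled synthetic RGB-D scenes for exercising the outlier-removal pipeline.

The generator emulates the scanning geometry the color-guided filter is
designed for: a bright dome-shaped object resting on a darker planar
platform, viewed by a depth sensor and an RGB sensor separated by a small
horizontal baseline. Three kinds of depth outliers are injected, mirroring
the standard taxonomy for structured-light scans:

* type I  — sparse isolated single-pixel outliers floating off the surface;
* type II — compact outlier clusters detached from the object silhouette;
* type III — outlier clusters contiguous with the object silhouette.

Outlier pixels receive low-value (dark) colors near the platform albedo by
default, emulating the real mechanism that makes a V-channel threshold
remove them: outliers arise at silhouettes and shadows and map to dark
background colors. The ``outlier_albedo`` knob can be raised to synthesize
the documented failure mode (bright outliers on a low-contrast surface).

Everything is deterministic for a fixed seed: depth, color, labels, and all
downstream pipeline outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import SceneConfigError
from .geometry import CameraIntrinsics, RigidTransform
from .images import ColorImage, DepthImage

__all__ = ["Label", "SceneConfig", "SyntheticFrame", "generate_scene", "inject_outliers"]


class Label(IntEnum):
    """Per-pixel ground-truth label."""

    INVALID = 0
    PLATFORM = 1
    OBJECT = 2
    OUTLIER_I = 3
    OUTLIER_II = 4
    OUTLIER_III = 5


OUTLIER_LABELS = (Label.OUTLIER_I, Label.OUTLIER_II, Label.OUTLIER_III)


def _default_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=150.0, fy=150.0, cx=80.0, cy=60.0, width=160, height=120)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Albedos are mean V (value-channel) targets in [0, 1]; ``light_gain``
    multiplies all colors before clipping, emulating strong/weak lighting.
    The contrast between object and platform albedo is what the V-threshold
    segmentation exploits; shrink it (e.g. to 0.05) to emulate a dark,
    low-contrast object surface where the method is expected to fail.
    """

    width: int = 160
    height: int = 120
    # Geometry (meters): dome semi-axes (x, y), dome height, platform depth.
    object_semi_axes: tuple[float, float] = (0.16, 0.12)
    object_height: float = 0.08
    platform_depth: float = 0.6
    # Photometry.
    object_albedo: float = 0.8
    platform_albedo: float = 0.2
    outlier_albedo: Optional[float] = None  # None -> platform_albedo
    light_gain: float = 1.0
    color_noise_sd: float = 0.02
    depth_noise_sd: float = 0.002
    # Outliers.
    n_type1: int = 200
    n_type2_clusters: int = 3
    type2_cluster_size: int = 12
    n_type3_clusters: int = 2
    type3_cluster_size: int = 10
    type2_gap_px: int = 6
    type1_margin_px: int = 4
    border_margin_px: int = 12
    outlier_depth_offset: tuple[float, float] = (0.03, 0.15)
    type3_depth_offset: tuple[float, float] = (0.01, 0.05)
    # Cameras.
    depth_intrinsics: CameraIntrinsics = field(default_factory=_default_intrinsics)
    color_intrinsics: CameraIntrinsics = field(default_factory=_default_intrinsics)
    baseline_t: tuple[float, float, float] = (0.025, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise SceneConfigError("frame must be at least 16 x 16")
        for name in ("object_albedo", "platform_albedo"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise SceneConfigError(f"{name} must lie in [0, 1], got {a}")
        if self.outlier_albedo is not None and not 0.0 <= self.outlier_albedo <= 1.0:
            raise SceneConfigError(f"outlier_albedo must lie in [0, 1], got {self.outlier_albedo}")
        for name in ("n_type1", "n_type2_clusters", "n_type3_clusters"):
            if getattr(self, name) < 0:
                raise SceneConfigError(f"{name} must be >= 0")
        if self.type2_cluster_size < 1 or self.type3_cluster_size < 1:
            raise SceneConfigError("cluster sizes must be >= 1")
        if (self.depth_intrinsics.width, self.depth_intrinsics.height) != (
            self.width,
            self.height,
        ):
            raise SceneConfigError("depth intrinsics size must match the frame size")
        # The dome footprint (at its closest, largest-looking depth) must fit
        # inside the frame with room for the border margin.
        K = self.depth_intrinsics
        z_top = self.platform_depth - self.object_height
        if z_top <= 0:
            raise SceneConfigError("object height must be smaller than the platform depth")
        ax_px = K.fx * self.object_semi_axes[0] / z_top
        ay_px = K.fy * self.object_semi_axes[1] / z_top
        if (
            K.cx - ax_px < self.border_margin_px
            or K.cx + ax_px > self.width - 1 - self.border_margin_px
            or K.cy - ay_px < self.border_margin_px
            or K.cy + ay_px > self.height - 1 - self.border_margin_px
        ):
            raise SceneConfigError("object footprint exceeds the frame (minus border margin)")

    @property
    def contrast_gap(self) -> float:
        """Object minus platform albedo — the contrast segmentation relies on."""
        return self.object_albedo - self.platform_albedo

    def with_contrast_gap(self, gap: float) -> "SceneConfig":
        """Copy with the object albedo set to ``platform_albedo + gap``."""
        return replace(self, object_albedo=self.platform_albedo + gap)

    @property
    def extrinsics(self) -> RigidTransform:
        """Depth-to-color transform (pure horizontal baseline by default)."""
        return RigidTransform(np.eye(3), np.asarray(self.baseline_t, dtype=float))


@dataclass
class SyntheticFrame:
    """One generated RGB-D frame with per-pixel ground truth.

    ``base_v`` is the generator's internal photometric model: the per-depth-
    pixel value-channel target before the light gain and clipping are
    applied. ``labels`` follows :class:`Label`; ``cluster_sizes`` records the
    pixel count of each injected type II/III cluster.
    """

    depth: DepthImage
    color: ColorImage
    labels: np.ndarray
    base_v: np.ndarray
    config: SceneConfig
    cluster_sizes: dict = field(default_factory=dict)

    @property
    def cameras(self) -> tuple[CameraIntrinsics, CameraIntrinsics, RigidTransform]:
        return (self.config.depth_intrinsics, self.config.color_intrinsics, self.config.extrinsics)

    def unclipped_v(self) -> np.ndarray:
        """Value-channel targets after light gain but before clipping."""
        return self.base_v * self.config.light_gain

    def outlier_mask(self) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in OUTLIER_LABELS])


def _render_color(
    depth_values: np.ndarray,
    labels: np.ndarray,
    base_v: np.ndarray,
    cfg: SceneConfig,
) -> ColorImage:
    """Paint the color image by forward-splatting every depth pixel.

    Each depth pixel is deprojected, moved into the color sensor frame,
    projected, and its color written to the nearest color pixel with a
    z-buffer (nearest depth wins; ties by larger flat pixel index).
    Unpainted color pixels are filled with the platform color. Object pixels
    get a slightly warm tint, everything else neutral gray; in both cases
    the value channel equals the (gained, clipped) base_v exactly.
    """
    Kd, Kc, T = cfg.depth_intrinsics, cfg.color_intrinsics, cfg.extrinsics
    h, w = depth_values.shape
    v_grid, u_grid = np.mgrid[0:h, 0:w].astype(float)
    z = depth_values
    valid = z > 0
    pts = np.stack([(u_grid - Kd.cx) * z / Kd.fx, (v_grid - Kd.cy) * z / Kd.fy, z], axis=-1)
    pts_c = T.apply(pts)
    z2 = pts_c[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u2 = Kc.fx * pts_c[..., 0] / np.where(z2 > 0, z2, 1.0) + Kc.cx
        v2 = Kc.fy * pts_c[..., 1] / np.where(z2 > 0, z2, 1.0) + Kc.cy
    ui = np.copysign(np.floor(np.abs(u2) + 0.5), u2).astype(int)
    vi = np.copysign(np.floor(np.abs(v2) + 0.5), v2).astype(int)
    ok = valid & (z2 > 0) & (ui >= 0) & (ui < Kc.width) & (vi >= 0) & (vi < Kc.height)

    value = np.clip(base_v * cfg.light_gain, 0.0, 1.0)
    tint = np.where(
        (labels == Label.OBJECT)[..., None],
        np.array([1.0, 0.96, 0.88]),
        np.array([1.0, 1.0, 1.0]),
    )
    rgb8 = np.floor(value[..., None] * tint * 255.0 + 0.5).astype(np.uint8)

    bg = int(np.floor(np.clip(cfg.platform_albedo * cfg.light_gain, 0.0, 1.0) * 255.0 + 0.5))
    img = np.full((Kc.height, Kc.width, 3), bg, dtype=np.uint8)

    src = np.flatnonzero(ok.ravel())
    # Paint far-to-near so the nearest surface wins each color pixel.
    order = src[np.argsort(-z.ravel()[src], kind="stable")]
    img[vi.ravel()[order], ui.ravel()[order]] = rgb8.reshape(-1, 3)[order]
    return ColorImage(img, normalized=False)


def _disk_offsets(radius: int) -> np.ndarray:
    """Window offsets sorted by distance from the center (ties: row, col)."""
    dv, du = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = dv**2 + du**2
    order = np.lexsort((du.ravel(), dv.ravel(), d2.ravel()))
    return np.stack([dv.ravel()[order], du.ravel()[order]], axis=1)


def _grow_cluster(
    seed_rc: tuple[int, int],
    size: int,
    allowed: np.ndarray,
) -> Optional[np.ndarray]:
    """Pick ``size`` allowed pixels forming a compact blob around a seed."""
    h, w = allowed.shape
    radius = int(np.ceil(np.sqrt(size))) + 2
    offs = _disk_offsets(radius)
    rr = seed_rc[0] + offs[:, 0]
    cc = seed_rc[1] + offs[:, 1]
    inb = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[inb], cc[inb]
    good = allowed[rr, cc]
    if good.sum() < size:
        return None
    sel = np.flatnonzero(good)[:size]
    return np.stack([rr[sel], cc[sel]], axis=1)


def inject_outliers(frame: SyntheticFrame, cfg: Optional[SceneConfig] = None) -> SyntheticFrame:
    """Inject type I/II/III outliers into a clean frame and re-render color.

    Placement rules (all randomness from ``cfg.seed``):

    * type I pixels sit on the platform at least ``type1_margin_px`` from
      any object pixel, pairwise separated by >= 3 px, with depth pulled
      toward the camera by a random offset;
    * type II clusters of exactly ``type2_cluster_size`` pixels stay at
      least ``type2_gap_px`` from every object pixel;
    * type III clusters of exactly ``type3_cluster_size`` pixels are seeded
      8-adjacent to the object silhouette and hug the local surface depth.

    All outlier pixels get base-V values near ``outlier_albedo`` (default:
    the platform albedo), so a correct V-threshold classifies them as
    background. Raises :class:`SceneConfigError` when the platform area
    cannot host the requested outliers.
    """
    cfg = cfg if cfg is not None else frame.config
    rng = np.random.default_rng([max(int(cfg.seed), 0), 1])
    labels = frame.labels.copy()
    depth = frame.depth.values.copy()
    base_v = frame.base_v.copy()
    cluster_sizes: dict = {"II": [], "III": []}
    h, w = labels.shape

    object_mask = labels == Label.OBJECT
    dist_to_object = ndimage.distance_transform_edt(~object_mask)
    interior = np.zeros((h, w), dtype=bool)
    m = cfg.border_margin_px
    interior[m : h - m, m : w - m] = True
    platform = (labels == Label.PLATFORM) & interior
    occupied = np.zeros((h, w), dtype=bool)

    out_albedo = cfg.outlier_albedo if cfg.outlier_albedo is not None else cfg.platform_albedo
    lo, hi = cfg.outlier_depth_offset

    def paint(rows: np.ndarray, cols: np.ndarray, label: Label, z_off: np.ndarray) -> None:
        labels[rows, cols] = label
        depth[rows, cols] = depth[rows, cols] - z_off
        base_v[rows, cols] = out_albedo + rng.normal(0.0, cfg.color_noise_sd, size=len(rows))
        occupied[rows, cols] = True

    # --- type II: detached compact clusters -------------------------------
    gap = cfg.type2_gap_px
    for _ in range(cfg.n_type2_clusters):
        allowed = platform & (dist_to_object >= gap) & ~occupied
        cand = np.flatnonzero(allowed.ravel())
        placed = False
        for idx in rng.permutation(cand)[:200]:
            seed_rc = (idx // w, idx % w)
            blob = _grow_cluster(seed_rc, cfg.type2_cluster_size, allowed)
            if blob is not None:
                z_off = rng.uniform(lo, hi) + rng.normal(0, 0.002, size=len(blob))
                paint(blob[:, 0], blob[:, 1], Label.OUTLIER_II, z_off)
                # Keep later clusters from merging with this one.
                occupied[
                    max(blob[:, 0].min() - 2, 0) : blob[:, 0].max() + 3,
                    max(blob[:, 1].min() - 2, 0) : blob[:, 1].max() + 3,
                ] = True
                cluster_sizes["II"].append(len(blob))
                placed = True
                break
        if not placed:
            raise SceneConfigError("not enough free platform pixels for a type II cluster")

    # --- type III: clusters attached to the object silhouette -------------
    ring = ndimage.binary_dilation(object_mask, structure=np.ones((3, 3), dtype=bool))
    ring &= ~object_mask
    for _ in range(cfg.n_type3_clusters):
        allowed = ~object_mask & interior & ~occupied
        cand = np.flatnonzero((ring & allowed).ravel())
        placed = False
        for idx in rng.permutation(cand)[:200]:
            seed_rc = (idx // w, idx % w)
            blob = _grow_cluster(seed_rc, cfg.type3_cluster_size, allowed)
            if blob is not None:
                lo3, hi3 = cfg.type3_depth_offset
                z_off = rng.uniform(lo3, hi3) + rng.normal(0, 0.001, size=len(blob))
                paint(blob[:, 0], blob[:, 1], Label.OUTLIER_III, z_off)
                occupied[
                    max(blob[:, 0].min() - 2, 0) : blob[:, 0].max() + 3,
                    max(blob[:, 1].min() - 2, 0) : blob[:, 1].max() + 3,
                ] = True
                cluster_sizes["III"].append(len(blob))
                placed = True
                break
        if not placed:
            raise SceneConfigError("no room for a type III cluster at the silhouette")

    # --- type I: sparse isolated pixels -----------------------------------
    if cfg.n_type1 > 0:
        allowed = platform & (dist_to_object >= cfg.type1_margin_px) & ~occupied
        cand = rng.permutation(np.flatnonzero(allowed.ravel()))
        blocked = occupied.copy()
        rows, cols = [], []
        for idx in cand:
            r, c = idx // w, idx % w
            if blocked[r, c]:
                continue
            rows.append(r)
            cols.append(c)
            blocked[max(r - 3, 0) : r + 4, max(c - 3, 0) : c + 4] = True
            if len(rows) == cfg.n_type1:
                break
        if len(rows) < cfg.n_type1:
            raise SceneConfigError(
                f"only {len(rows)} free pixels for {cfg.n_type1} type I outliers"
            )
        rows = np.array(rows)
        cols = np.array(cols)
        z_off = rng.uniform(lo, hi, size=len(rows))
        paint(rows, cols, Label.OUTLIER_I, z_off)

    color = _render_color(depth, labels, base_v, cfg)
    return SyntheticFrame(
        depth=DepthImage(depth, depth_scale=frame.depth.depth_scale),
        color=color,
        labels=labels,
        base_v=base_v,
        config=cfg,
        cluster_sizes=cluster_sizes,
    )


def generate_scene(cfg: SceneConfig) -> SyntheticFrame:
    """Render a full labeled scene: dome on platform, noise, outliers, color.

    Deterministic for a fixed ``cfg.seed``. Equivalent to building the
    outlier-free scene and then calling :func:`inject_outliers` with the
    same config.
    """
    rng = np.random.default_rng([max(int(cfg.seed), 0), 0])
    K = cfg.depth_intrinsics
    h, w = cfg.height, cfg.width
    v_grid, u_grid = np.mgrid[0:h, 0:w].astype(float)
    zp = cfg.platform_depth
    X = (u_grid - K.cx) * zp / K.fx
    Y = (v_grid - K.cy) * zp / K.fy
    ax, ay = cfg.object_semi_axes
    e = (X / ax) ** 2 + (Y / ay) ** 2
    inside = e < 1.0
    depth = np.full((h, w), zp)
    depth[inside] = zp - cfg.object_height * np.sqrt(1.0 - e[inside])
    labels = np.where(inside, int(Label.OBJECT), int(Label.PLATFORM)).astype(np.int64)

    depth = depth + rng.normal(0.0, cfg.depth_noise_sd, size=depth.shape)
    albedo = np.where(inside, cfg.object_albedo, cfg.platform_albedo)
    base_v = albedo + rng.normal(0.0, cfg.color_noise_sd, size=depth.shape)

    frame = SyntheticFrame(
        depth=DepthImage(depth),
        color=_render_color(depth, labels, base_v, cfg),
        labels=labels,
        base_v=base_v,
        config=cfg,
    )
    return inject_outliers(frame, cfg)
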