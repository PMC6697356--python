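"""HSV conversion, Otsu thresholding of the V channel, and mask refinement.

The central idea of the filter: outliers in an RGB-D scan of a bright object
on a dark platform arise at silhouettes and shadows and therefore map to
dark background colors. Converting the mapping image to HSV and thresholding
the value channel V = max(R, G, B) — which is far less sensitive to light
intensity than raw RGB — separates the bright object from dark platform,
shadow and outlier pixels with a single adaptive threshold chosen by Otsu's
between-class-variance criterion. The binary mask is then cleaned up by
morphological closing, interior hole filling, and a minimum-area rule, and
finally drives the point-cloud extraction.

All thresholding happens on quantized gray levels (default L = 256,
0-based), so 8-bit inputs round-trip exactly: the level of a pixel is its
maximum channel byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogramError,
    DomainError,
    EmptyHistogramError,
    ShapeError,
)
from .images import ColorImage

__all__ = [
    "HsvImage",
    "GrayHistogram",
    "OtsuResult",
    "normalize_rgb",
    "rgb_to_hsv",
    "quantize_v",
    "v_histogram",
    "between_class_variance",
    "otsu_threshold",
    "binarize",
    "refine_mask",
    "default_area_threshold",
]


@dataclass
class HsvImage:
    """Per-pixel hue [0, 360), saturation [0, 1] and value [0, 1] grids.

    ``valid`` is inherited from the mapping image; invalid pixels hold
    H = S = V = 0.
    """

    H: np.ndarray
    S: np.ndarray
    V: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.V.shape


@dataclass
class GrayHistogram:
    """Counts of quantized gray levels over the valid pixels of one image."""

    counts: np.ndarray
    L: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (self.L,):
            raise ShapeError(f"counts must have shape ({self.L},), got {c.shape}")
        if np.any(c < 0):
            raise DomainError("histogram counts must be non-negative")
        self.counts = c

    @property
    def N(self) -> int:
        """Total number of counted pixels."""
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """p_i = n_i / N; sums to 1."""
        return self.counts / self.N


@dataclass
class OtsuResult:
    """Selected threshold level, its between-class variance, and the full curve.

    ``k_opt`` is the 0-based level maximizing sigma^2(k) over k = 0..L-2;
    class 0 holds levels <= k, class 1 the rest. Ties go to the smallest k.
    """

    k_opt: int
    sigma2: float
    curve: np.ndarray


def normalize_rgb(color: ColorImage) -> ColorImage:
    """Divide 8-bit channels by 255 exactly, yielding values in [0, 1].

    An already-normalized input is returned unchanged with a warning.
    """
    if color.normalized:
        warnings.warn("normalize_rgb called on an already-normalized image; no-op", stacklevel=2)
        return color
    return ColorImage(color.values.astype(float) / 255.0, normalized=True)


def rgb_to_hsv(color: ColorImage, valid: Optional[np.ndarray] = None) -> HsvImage:
    """Convert a normalized RGB image to HSV.

    Definitions (all on channels in [0, 1]):

    * ``V = max(R, G, B)``
    * ``S = (V - min(R, G, B)) / V`` if V != 0, else 0
    * ``H`` in degrees from the branch of the channel attaining V
      (priority R, then G, then B on ties), negative hues wrapped by +360.

    Achromatic pixels (V == min) have an undefined hue; H = 0 is used —
    harmless here since only V is thresholded downstream. Invalid pixels get
    H = S = V = 0.
    """
    if not color.normalized:
        raise DomainError("rgb_to_hsv requires a normalized image; call normalize_rgb first")
    vals = color.values
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise DomainError("normalized channels must lie in [0, 1]")
    R, G, B = vals[..., 0], vals[..., 1], vals[..., 2]
    V = np.max(vals, axis=-1)
    mn = np.min(vals, axis=-1)
    C = V - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(V > 0, C / np.where(V > 0, V, 1.0), 0.0)
        Csafe = np.where(C > 0, C, 1.0)
        r_is_max = R == V
        g_is_max = (G == V) & ~r_is_max
        H = np.where(
            r_is_max,
            60.0 * (G - B) / Csafe,
            np.where(
                g_is_max,
                60.0 * (2.0 + (B - R) / Csafe),
                60.0 * (4.0 + (R - G) / Csafe),
            ),
        )
    H = np.where(H < 0, H + 360.0, H)
    H = np.where(C > 0, H, 0.0)

    if valid is None:
        valid = np.ones(V.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != V.shape:
        raise ShapeError(f"valid shape {valid.shape} != image shape {V.shape}")
    H = np.where(valid, H, 0.0)
    S = np.where(valid, S, 0.0)
    V = np.where(valid, V, 0.0)
    return HsvImage(H=H, S=S, V=V, valid=valid)


def quantize_v(V: np.ndarray, L: int = 256) -> np.ndarray:
    """Quantize V in [0, 1] to integer levels 0..L-1 (round half up).

    level = floor(V * (L - 1) + 0.5); 8-bit inputs round-trip exactly, the
    level being the pixel's maximum channel byte.
    """
    V = np.asarray(V, dtype=float)
    levels = np.floor(V * (L - 1) + 0.5).astype(np.int64)
    return np.clip(levels, 0, L - 1)


def v_histogram(V: np.ndarray, valid: np.ndarray, L: int = 256) -> GrayHistogram:
    """Histogram of quantized V levels over valid pixels only.

    Invalid pixels (no depth, outside the bounding box, no color mapping)
    are excluded: they would flood level 0 and corrupt the threshold.
    """
    if L < 2:
        raise DomainError(f"need at least 2 levels, got L={L}")
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != np.shape(V):
        raise ShapeError(f"valid shape {valid.shape} != V shape {np.shape(V)}")
    if not valid.any():
        raise EmptyHistogramError("no valid pixels to histogram")
    levels = quantize_v(np.asarray(V)[valid], L)
    counts = np.bincount(levels, minlength=L)
    return GrayHistogram(counts=counts, L=L)


def _cumulative_moments(h: GrayHistogram) -> tuple[np.ndarray, np.ndarray, float]:
    """omega(k), mu(k) cumulative over levels 0..k, and the global mean mu_T."""
    p = h.probabilities
    i = np.arange(h.L, dtype=float)
    omega = np.cumsum(p)
    mu = np.cumsum(i * p)
    return omega, mu, float(mu[-1])


def between_class_variance(h: GrayHistogram, k: int) -> float:
    """Between-class variance sigma^2(k) of the split {0..k} vs {k+1..L-1}.

    Computed in the closed form
    ``[mu_T * omega(k) - mu(k)]^2 / (omega(k) * (1 - omega(k)))``,
    which equals ``omega0 (mu0 - mu_T)^2 + omega1 (mu1 - mu_T)^2``. Defined
    as 0 whenever one class is empty (omega in {0, 1}).
    """
    if not 0 <= k <= h.L - 2:
        raise DomainError(f"k must lie in [0, {h.L - 2}], got {k}")
    omega, mu, mu_T = _cumulative_moments(h)
    w = omega[k]
    if w <= 0.0 or w >= 1.0:
        return 0.0
    return float((mu_T * w - mu[k]) ** 2 / (w * (1.0 - w)))


def otsu_threshold(h: GrayHistogram) -> OtsuResult:
    """Maximize the between-class variance over all splits.

    Scans k = 0..L-2 and returns the argmax; ties are broken by the
    smallest k, so the result is deterministic. Requires histogram mass at
    two or more distinct levels.
    """
    if int(np.count_nonzero(h.counts)) < 2:
        raise DegenerateHistogramError(
            "histogram has mass at fewer than 2 levels; no threshold separates two classes"
        )
    omega, mu, mu_T = _cumulative_moments(h)
    w = omega[: h.L - 1]
    m = mu[: h.L - 1]
    denom = w * (1.0 - w)
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = np.where(denom > 0, (mu_T * w - m) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    k_opt = int(np.argmax(curve))  # first occurrence = smallest k on ties
    return OtsuResult(k_opt=k_opt, sigma2=float(curve[k_opt]), curve=curve)


def binarize(V: np.ndarray, valid: np.ndarray, k_opt: int, L: int = 256) -> np.ndarray:
    """Threshold quantized V levels into a {0, 1} target mask.

    A pixel is background (0) when its level is strictly below ``k_opt``
    and target (1) otherwise; a level exactly equal to the threshold is
    target. Invalid pixels are background.
    """
    if not 0 <= k_opt <= L - 2:
        raise DomainError(f"k_opt must lie in [0, {L - 2}], got {k_opt}")
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != np.shape(V):
        raise ShapeError(f"valid shape {valid.shape} != V shape {np.shape(V)}")
    levels = quantize_v(np.asarray(V), L)
    return ((levels >= k_opt) & valid).astype(np.uint8)


def default_area_threshold(height: int, width: int, reference: int = 5000) -> int:
    """Scale the minimum-component-area threshold to the frame resolution.

    ``reference`` is the area threshold appropriate for a 640 x 480 frame
    (a few thousand pixels, i.e. clearly smaller than the scanned object's
    silhouette); other resolutions scale by their pixel count.
    """
    return int(round(reference * (height * width) / (640 * 480)))


def refine_mask(mask: np.ndarray, kernel: int = 3, s_th: int = 0) -> np.ndarray:
    """Clean a binary mask: closing, hole filling, minimum-area filtering.

    1. Morphological closing (dilation then erosion) with a square
       ``kernel`` x ``kernel`` structuring element seals pixel-scale gaps.
    2. Interior holes — background regions not connected to the image
       border (4-connected background) — are filled with 1.
    3. 8-connected components of 1s with area strictly below ``s_th``
       pixels are erased; only components at least as large as the scanned
       object's expected silhouette survive.

    With ``kernel=1``, ``s_th=0`` and no holes the mask passes through
    unchanged.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise DomainError(f"kernel must be odd and >= 1, got {kernel}")
    if s_th < 0:
        raise DomainError(f"s_th must be >= 0, got {s_th}")
    m = np.asarray(mask).astype(bool)

    if kernel > 1:
        structure = np.ones((kernel, kernel), dtype=bool)
        m = ndimage.binary_closing(m, structure=structure)

    # Hole filling: flood the background from the border with 4-connectivity
    # (the complement of 8-connected foreground); unreached background is a hole.
    bg_labels, n_bg = ndimage.label(~m, structure=ndimage.generate_binary_structure(2, 1))
    if n_bg > 0:
        border = np.zeros_like(m)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        border_labels = np.unique(bg_labels[border & ~m])
        hole = (~m) & ~np.isin(bg_labels, border_labels)
        m = m | hole

    if s_th > 0:
        fg_labels, n_fg = ndimage.label(m, structure=np.ones((3, 3), dtype=bool))
        if n_fg > 0:
            areas = np.bincount(fg_labels.ravel())
            small = np.flatnonzero(areas < s_th)
            m = m & ~np.isin(fg_labels, small[small > 0])

    return m.astype(np.uint8)
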