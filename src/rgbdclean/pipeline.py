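"""End-to-end pipeline orchestration and removal-quality evaluation.

Stage order: align color to depth -> build organized cloud -> 3D bounding
box pre-filter -> normalize RGB -> HSV -> V histogram -> Otsu threshold ->
binarize -> mask refinement -> mask-based extraction. Every intermediate is
returned so each stage can be inspected or cross-checked.

Evaluation mirrors the standard comparison-table semantics: counts of
ground-truth noise points, points removed, noise points correctly removed,
and valid points (object or in-box platform) mistakenly removed, with the
identity ``removed == noise_removed + mistakenly_removed`` holding by
construction. Platform points inside the box count as valid, so removing
them is "mistaken" — matching the observation that contact-surface points
near the platform are the typical collateral of the color threshold.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import align_color_to_depth, depth_to_cloud
from .cloud import (
    BoundingBox3D,
    ExtractionResult,
    OrganizedPointCloud,
    bbox_filter,
    extract_by_mask,
)
from .errors import (
    DegenerateHistogramError,
    DegenerateSegmentationError,
    EmptyHistogramError,
    EvaluationError,
)
from .geometry import CameraIntrinsics, RigidTransform
from .images import ColorImage, DepthImage, MappingImage
from .segmentation import (
    GrayHistogram,
    HsvImage,
    OtsuResult,
    binarize,
    default_area_threshold,
    normalize_rgb,
    otsu_threshold,
    refine_mask,
    rgb_to_hsv,
    v_histogram,
)
from .synthetic import Label

__all__ = ["PipelineParams", "PipelineResult", "FilterReport", "run_pipeline", "evaluate_removal"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable pipeline parameters.

    ``box=None`` disables the bounding-box pre-filter (full frustum).
    ``s_th=None`` uses the resolution-scaled default minimum component area.
    ``refine=False`` extracts with the raw threshold mask (no morphology).
    """

    box: Optional[BoundingBox3D] = None
    levels: int = 256
    closing_kernel: int = 3
    s_th: Optional[int] = None
    refine: bool = True


@dataclass
class PipelineResult:
    """All pipeline outputs and intermediates for one frame."""

    mapping: MappingImage
    cloud: OrganizedPointCloud
    hsv: HsvImage
    histogram: GrayHistogram
    otsu: OtsuResult
    raw_mask: np.ndarray
    refined_mask: np.ndarray
    extraction: ExtractionResult
    stage_seconds: dict = field(default_factory=dict)

    @property
    def k_opt(self) -> int:
        return self.otsu.k_opt


@dataclass
class FilterReport:
    """Removal-quality counts for one filtered frame.

    ``size_points_removed == size_valid_noise_removed +
    size_mistakenly_removed`` always. ``wall_time`` is informational only.
    """

    size_noise_points: int
    size_points_removed: int
    size_valid_noise_removed: int
    size_mistakenly_removed: int
    wall_time: float = 0.0
    removed_by_type: dict = field(default_factory=dict)
    noise_by_type: dict = field(default_factory=dict)

    def noise_removal_fraction(self) -> float:
        """Fraction of ground-truth noise points removed (1.0 = all)."""
        if self.size_noise_points == 0:
            return 1.0
        return self.size_valid_noise_removed / self.size_noise_points


def run_pipeline(
    depth: DepthImage,
    color: ColorImage,
    K_depth: CameraIntrinsics,
    K_color: CameraIntrinsics,
    T_depth_to_color: RigidTransform,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run the full color-guided outlier-removal pipeline on one frame.

    Deterministic for fixed inputs. Raises
    :class:`DegenerateSegmentationError` (naming the stage) when the valid
    pixels carry no usable V contrast — e.g. a uniform V level.
    """
    timings: dict = {}

    t0 = time.perf_counter()
    mapping = align_color_to_depth(depth, color, K_depth, K_color, T_depth_to_color)
    timings["align"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cloud = depth_to_cloud(depth, K_depth, mapping)
    if params.box is not None:
        cloud, mapping = bbox_filter(cloud, mapping, params.box)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    norm = mapping.color if mapping.color.normalized else normalize_rgb(mapping.color)
    hsv = rgb_to_hsv(norm, valid=cloud.valid & mapping.valid)
    timings["hsv"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        hist = v_histogram(hsv.V, hsv.valid, params.levels)
        otsu = otsu_threshold(hist)
    except EmptyHistogramError as exc:
        raise DegenerateSegmentationError("histogram", str(exc)) from exc
    except DegenerateHistogramError as exc:
        raise DegenerateSegmentationError("otsu", str(exc)) from exc
    timings["otsu"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw_mask = binarize(hsv.V, hsv.valid, otsu.k_opt, params.levels)
    if params.refine:
        s_th = (
            params.s_th
            if params.s_th is not None
            else default_area_threshold(*depth.shape)
        )
        mask = refine_mask(raw_mask, kernel=params.closing_kernel, s_th=s_th)
    else:
        mask = raw_mask
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    extraction = extract_by_mask(cloud, mask)
    timings["extract"] = time.perf_counter() - t0

    return PipelineResult(
        mapping=mapping,
        cloud=cloud,
        hsv=hsv,
        histogram=hist,
        otsu=otsu,
        raw_mask=raw_mask,
        refined_mask=mask,
        extraction=extraction,
        stage_seconds=timings,
    )


_NOISE_LABELS = (int(Label.OUTLIER_I), int(Label.OUTLIER_II), int(Label.OUTLIER_III))
_VALID_LABELS = (int(Label.PLATFORM), int(Label.OBJECT))


def evaluate_indices(
    labels: np.ndarray,
    target_index: np.ndarray,
    removed_index: np.ndarray,
    wall_time: float = 0.0,
) -> FilterReport:
    """Score a target/removed partition (flat pixel indices) against labels."""
    flat = np.asarray(labels).ravel()
    evaluated = np.concatenate([np.asarray(target_index), np.asarray(removed_index)]).astype(int)
    ev_labels = flat[evaluated]
    if np.any(ev_labels == int(Label.INVALID)):
        raise EvaluationError("ground truth labels an evaluated point as invalid")

    rem_labels = flat[np.asarray(removed_index, dtype=int)]
    is_noise = np.isin(ev_labels, _NOISE_LABELS)
    rem_noise = np.isin(rem_labels, _NOISE_LABELS)

    noise_by_type = {
        Label(lab).name: int(np.count_nonzero(ev_labels == lab)) for lab in _NOISE_LABELS
    }
    removed_by_type = {
        Label(lab).name: int(np.count_nonzero(rem_labels == lab)) for lab in _NOISE_LABELS
    }
    return FilterReport(
        size_noise_points=int(is_noise.sum()),
        size_points_removed=int(len(rem_labels)),
        size_valid_noise_removed=int(rem_noise.sum()),
        size_mistakenly_removed=int(len(rem_labels) - rem_noise.sum()),
        wall_time=wall_time,
        removed_by_type=removed_by_type,
        noise_by_type=noise_by_type,
    )


def evaluate_removal(
    labels: np.ndarray,
    result: ExtractionResult,
    wall_time: float = 0.0,
) -> FilterReport:
    """Score an extraction against per-pixel ground-truth labels.

    Every valid point of the evaluated cloud must carry a non-invalid
    label. Noise = the three outlier types; valid = object and platform.
    """
    return evaluate_indices(labels, result.target_index, result.removed_index, wall_time)
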