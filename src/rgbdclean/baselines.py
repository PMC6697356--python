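"""Statistical (SOR) and radius (ROR) outlier removal baselines.

These are the two classical neighborhood-density filters the color-guided
pipeline is compared against. Both are defined on unorganized clouds, use a
k-d tree internally, and are contractually equivalent to an all-pairs
brute-force evaluation:

* SOR removes a point when its mean distance to its k nearest neighbors
  exceeds the global mean of those per-point means by more than
  ``sigma_mult`` population standard deviations.
* ROR removes a point when fewer than ``num`` other points lie within
  radius ``r`` of it.

Reference working parameters for a dense structured-light scan
(sub-millimeter point pitch): SOR k=15, sigma=0.5; ROR r=0.002 m, num=12.
For sparser clouds scale ``r`` with the point pitch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial import cKDTree

from .cloud import UnorganizedCloud
from .errors import DomainError, InsufficientPointsError

__all__ = ["BaselineParams", "sor_filter", "ror_filter"]


@dataclass(frozen=True)
class BaselineParams:
    """Bundle of baseline-filter parameters (defaults from dense-scan use)."""

    sor_k: int = 15
    sor_sigma: float = 0.5
    ror_r: float = 0.002
    ror_num: int = 12

    def __post_init__(self) -> None:
        if self.sor_k < 1:
            raise DomainError(f"sor_k must be >= 1, got {self.sor_k}")
        if self.sor_sigma <= 0:
            raise DomainError(f"sor_sigma must be > 0, got {self.sor_sigma}")
        if self.ror_r <= 0:
            raise DomainError(f"ror_r must be > 0, got {self.ror_r}")
        if self.ror_num < 1:
            raise DomainError(f"ror_num must be >= 1, got {self.ror_num}")


def _as_points(cloud: Union[UnorganizedCloud, np.ndarray]) -> np.ndarray:
    if isinstance(cloud, UnorganizedCloud):
        return cloud.points
    return np.asarray(cloud, dtype=float).reshape(-1, 3)


def sor_filter(
    cloud: Union[UnorganizedCloud, np.ndarray],
    k: int = 15,
    sigma_mult: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Statistical outlier removal.

    For each point, the mean Euclidean distance d_i to its k nearest
    neighbors (self excluded) is computed; point i is removed iff
    ``d_i > mean(d) + sigma_mult * std(d)`` with the population standard
    deviation. Returns ``(kept_indices, removed_indices)``, a partition of
    the index set.
    """
    pts = _as_points(cloud)
    n = len(pts)
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if sigma_mult <= 0:
        raise DomainError(f"sigma_mult must be > 0, got {sigma_mult}")
    if n <= k:
        raise InsufficientPointsError(f"need more than k={k} points, got {n}")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)  # column 0 is the point itself
    d = dist[:, 1:].mean(axis=1)
    threshold = d.mean() + sigma_mult * d.std()  # population std (ddof=0)
    removed = np.flatnonzero(d > threshold)
    kept = np.flatnonzero(d <= threshold)
    return kept, removed


def ror_filter(
    cloud: Union[UnorganizedCloud, np.ndarray],
    r: float = 0.002,
    num: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius outlier removal.

    A point is kept iff at least ``num`` *other* points lie within distance
    ``<= r``. Returns ``(kept_indices, removed_indices)``.
    """
    pts = _as_points(cloud)
    if r <= 0:
        raise DomainError(f"r must be > 0, got {r}")
    if num < 1:
        raise DomainError(f"num must be >= 1, got {num}")
    if len(pts) == 0:
        raise InsufficientPointsError("empty cloud")
    tree = cKDTree(pts)
    # Count includes the query point itself; subtract one for self-exclusion.
    counts = np.array([len(nb) - 1 for nb in tree.query_ball_point(pts, r)])
    kept = np.flatnonzero(counts >= num)
    removed = np.flatnonzero(counts < num)
    return kept, removed
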