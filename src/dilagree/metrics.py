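"""Contour agreement metrics on anisotropic voxel grids.

Four metrics quantify how well two lesion contours agree: the overlap-based
Dice coefficient ``2|A∩B|/(|A|+|B|)`` and Jaccard index ``|A∩B|/|A∪B|``, and
the boundary-distance-based 95th-percentile Hausdorff distance (HD95) and
mean distance to agreement (MDA), both in physical millimetres.

Conventions (documented because segmentation tools differ on them):

* A boundary point is the physical center of a true voxel with at least one
  false or out-of-grid face neighbour (6-connectivity); the grid edge counts
  as exposure.
* HD95 and MDA are computed on the *pooled* bidirectional multiset of
  nearest-boundary distances (A→B together with B→A), which makes both
  symmetric by construction; the percentile uses linear interpolation
  between closest order statistics.  At q=100 the pooled percentile equals
  the classical symmetric Hausdorff distance.
* Both masks empty → the metrics are undefined (error).  Exactly one empty →
  Dice and Jaccard are 0, distance metrics remain undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import BinaryMask, GridError

__all__ = [
    "UndefinedMetricError",
    "SurfaceDistanceSet",
    "PairMetrics",
    "dice",
    "jaccard",
    "extract_boundary",
    "surface_distances",
    "hausdorff_percentile",
    "mean_distance_to_agreement",
    "pair_metrics",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. empty masks)."""


@dataclass(frozen=True)
class SurfaceDistanceSet:
    """Directed nearest-boundary distances between two contours, in mm."""

    distances_ab: np.ndarray
    distances_ba: np.ndarray

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.distances_ab, self.distances_ba])


@dataclass(frozen=True)
class PairMetrics:
    """Bundle of the four agreement metrics for one contour pair."""

    dice: float
    jaccard: float
    hd95: float
    mda: float


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if a.geometry != b.geometry:
        raise GridError(
            f"mask geometries differ: {a.geometry} vs {b.geometry}"
        )
    if a.n_voxels == 0 and b.n_voxels == 0:
        raise UndefinedMetricError("both masks are empty")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap coefficient, by voxel counts."""
    _check_pair(a, b)
    inter = np.logical_and(a.voxels, b.voxels).sum()
    return float(2.0 * inter / (a.n_voxels + b.n_voxels))


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index (intersection over union), by voxel counts."""
    _check_pair(a, b)
    inter = np.logical_and(a.voxels, b.voxels).sum()
    union = np.logical_or(a.voxels, b.voxels).sum()
    return float(inter / union)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def extract_boundary(a: BinaryMask) -> np.ndarray:
    """Physical centers (mm) of face-exposed true voxels, shape (n, 3).

    A voxel is on the boundary when at least one of its six face neighbours
    is false or lies outside the grid.
    """
    if a.n_voxels == 0:
        raise UndefinedMetricError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(a.voxels, _FACE_STRUCT, border_value=0)
    idx = np.argwhere(a.voxels & ~interior)
    return a.geometry.index_to_physical(idx)


def surface_distances(a: BinaryMask, b: BinaryMask) -> SurfaceDistanceSet:
    """Euclidean nearest-neighbour distances between boundary point sets."""
    _check_pair(a, b)
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise UndefinedMetricError("surface distances need two non-empty masks")
    pa = extract_boundary(a)
    pb = extract_boundary(b)
    d_ab, _ = cKDTree(pb).query(pa, k=1)
    d_ba, _ = cKDTree(pa).query(pb, k=1)
    return SurfaceDistanceSet(distances_ab=d_ab, distances_ba=d_ba)


def hausdorff_percentile(s: SurfaceDistanceSet, q: float = 95.0) -> float:
    """q-th percentile (linear interpolation) of the pooled distance multiset.

    ``q=100`` equals the classical symmetric Hausdorff distance.
    """
    if not 0 < q <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {q}")
    pooled = s.pooled()
    if pooled.size == 0:
        raise UndefinedMetricError("empty distance set")
    return float(np.percentile(pooled, q, method="linear"))


def mean_distance_to_agreement(s: SurfaceDistanceSet) -> float:
    """Arithmetic mean of the pooled bidirectional distance multiset."""
    pooled = s.pooled()
    if pooled.size == 0:
        raise UndefinedMetricError("empty distance set")
    return float(pooled.mean())


def pair_metrics(a: BinaryMask, b: BinaryMask, q: float = 95.0) -> PairMetrics:
    """All four agreement metrics for one pair of contours."""
    s = surface_distances(a, b)
    return PairMetrics(
        dice=dice(a, b),
        jaccard=jaccard(a, b),
        hd95=hausdorff_percentile(s, q),
        mda=mean_distance_to_agreement(s),
    )
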