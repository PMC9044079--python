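"""Stage-plane removal (RANSAC) and single-grain region growing.

The stage the grains rest on is the dominant plane of the scene; it is
found by RANSAC over 3-point hypotheses, refined by least squares on the
inliers, and removed together with everything below it.  The remaining
multi-grain cloud is split into single grains by region growing over a
k-NN graph: growth starts from minimum-curvature seeds and crosses an
edge when the two surface normals deviate by less than an angle
threshold; clusters outside a size window are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud_io import PointCloud

__all__ = [
    "PlaneModel",
    "GrainSegment",
    "fit_stage_plane",
    "remove_stage",
    "segment_grains",
    "estimate_normals",
    "NoDominantPlaneError",
]


class NoDominantPlaneError(RuntimeError):
    """No plane hypothesis reached the minimum inlier fraction."""


@dataclass
class PlaneModel:
    """Plane n.x = offset with |n| = 1; ``inlier_indices`` into the fitted cloud."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            self.normal = self.normal / norm
        self.inlier_indices = np.asarray(self.inlier_indices, dtype=np.int64)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return points @ self.normal - self.offset


@dataclass
class GrainSegment:
    """One grain: integer ``label`` and point ``indices`` into the parent cloud."""

    label: int
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)


def fit_stage_plane(
    cloud: PointCloud,
    distance_threshold: float = 0.15,
    max_iterations: int = 1000,
    seed: int = 0,
    min_inlier_fraction: float = 0.2,
) -> PlaneModel:
    """RANSAC plane fit returning the maximal-inlier plane, LS-refined.

    Deterministic for a fixed ``seed``.  Raises :class:`NoDominantPlaneError`
    when the best inlier fraction is below ``min_inlier_fraction``.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("plane fitting needs at least 3 points")
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    rng = np.random.default_rng(seed)
    best_count = -1
    best = None
    for _ in range(max_iterations):
        i, j, k = rng.choice(n, size=3, replace=False)
        normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        offset = normal @ pts[i]
        count = np.count_nonzero(np.abs(pts @ normal - offset) <= distance_threshold)
        if count > best_count:
            best_count = count
            best = (normal, offset)
    if best is None or best_count < min_inlier_fraction * n:
        raise NoDominantPlaneError(
            f"no dominant plane: best inlier fraction "
            f"{max(best_count, 0) / n:.3f} < {min_inlier_fraction}"
        )
    normal, offset = best
    # least-squares refinement on the inliers, then recompute the inlier set
    for _ in range(2):
        inliers = np.flatnonzero(np.abs(pts @ normal - offset) <= distance_threshold)
        sub = pts[inliers]
        centroid = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
        normal = vt[-1] / np.linalg.norm(vt[-1])
        offset = normal @ centroid
    inliers = np.flatnonzero(np.abs(pts @ normal - offset) <= distance_threshold)
    # orient the normal toward the side holding the majority of off-plane
    # points (the grains sit on that side)
    outside = np.setdiff1d(np.arange(n), inliers, assume_unique=True)
    if outside.size and np.median(pts[outside] @ normal - offset) < 0:
        normal, offset = -normal, -offset
    return PlaneModel(normal=normal, offset=offset, inlier_indices=inliers)


def remove_stage(cloud: PointCloud, plane: PlaneModel, distance_threshold: float = 0.15) -> PointCloud:
    """Drop plane inliers and everything on or below the stage surface.

    Keeps points whose signed distance (positive on the grain side) exceeds
    ``distance_threshold``.  May return an empty cloud.
    """
    keep = plane.signed_distance(cloud.points) > distance_threshold
    return cloud.select(np.flatnonzero(keep))


def estimate_normals(points: np.ndarray, k_neighbors: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit normals and curvature from local PCA over k neighbours.

    The normal is the smallest-eigenvalue direction of the neighbourhood
    covariance; curvature is lambda_0 / (lambda_0 + lambda_1 + lambda_2).
    Normals are unoriented (sign is arbitrary).
    """
    n = len(points)
    if n <= k_neighbors:
        raise ValueError(f"need more than {k_neighbors} points to estimate normals")
    tree = cKDTree(points)
    _, nbr = tree.query(points, k=k_neighbors + 1)
    neigh = points[nbr]  # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k_neighbors + 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending per point
    normals = evecs[:, :, 0]
    total = evals.sum(axis=1)
    total[total <= 0] = 1.0
    curvature = evals[:, 0] / total
    return normals, curvature


def segment_grains(
    cloud: PointCloud,
    k_neighbors: int = 30,
    angle_threshold: float = 12.0,
    curvature_threshold: float = 1.0,
    min_cluster_size: int = 500,
    max_cluster_size: int = 20000,
) -> list[GrainSegment]:
    """Split a stage-free multi-grain cloud into single grains.

    Region growing seeded at minimum-curvature points; a neighbour joins the
    region when its normal deviates from the current point's by less than
    ``angle_threshold`` degrees (absolute dot product, since local-PCA
    normals are unoriented), and continues to grow the front while its own
    curvature is below ``curvature_threshold``.  Clusters outside
    [min_cluster_size, max_cluster_size] are discarded.  Labels are written
    back onto ``cloud.labels`` (-1 = unassigned/discarded).
    """
    pts = cloud.points
    n = len(pts)
    if n == 0:
        raise ValueError("cannot segment an empty cloud")
    normals, curvature = estimate_normals(pts, k_neighbors)
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=k_neighbors + 1)
    nbr = nbr[:, 1:]  # drop self
    cos_thr = np.cos(np.deg2rad(angle_threshold))

    order = np.argsort(curvature, kind="stable")
    assigned = np.full(n, -1, dtype=np.int64)
    clusters: list[np.ndarray] = []
    for seed in order:
        if assigned[seed] >= 0:
            continue
        label = len(clusters)
        assigned[seed] = label
        members = [seed]
        frontier = np.array([seed])
        while frontier.size:
            cand = nbr[frontier]                      # (f, k) neighbour ids
            src = np.repeat(frontier, nbr.shape[1])
            cand = cand.ravel()
            free = assigned[cand] < 0
            cand, src = cand[free], src[free]
            if cand.size == 0:
                break
            dots = np.abs(np.einsum("ij,ij->i", normals[cand], normals[src]))
            ok = dots >= cos_thr
            cand = cand[ok]
            if cand.size == 0:
                break
            cand = np.unique(cand)
            cand = cand[assigned[cand] < 0]
            assigned[cand] = label
            members.extend(cand.tolist())
            # only smooth (low-curvature) points keep growing the front
            frontier = cand[curvature[cand] < curvature_threshold]
        clusters.append(np.array(sorted(members), dtype=np.int64))

    segments: list[GrainSegment] = []
    labels = np.full(n, -1, dtype=np.int64)
    for members in clusters:
        if min_cluster_size <= members.size <= max_cluster_size:
            label = len(segments)
            labels[members] = label
            segments.append(GrainSegment(label=label, indices=members))
    cloud.labels = labels
    if not segments:
        warnings.warn("all clusters filtered out by size bounds", stacklevel=2)
    return segments
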