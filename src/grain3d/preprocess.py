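"""Raw-cloud preprocessing: voxel downsampling, outlier removal, PCA alignment.

The merged scanner cloud is thinned on a voxel grid (one centroid per
occupied cell), stripped of statistical outliers (mean k-NN distance
criterion), and rotated into its principal frame: the cloud is translated
to its centroid A and rotated by the matrix of covariance eigenvectors,
T_aligned = M (T0 - A), with axes ordered by descending variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud_io import PointCloud

__all__ = ["RigidTransform", "voxel_downsample", "remove_outliers", "pca_align"]


@dataclass
class RigidTransform:
    """Rotation + translation mapping parent coordinates into a local frame.

    ``apply``: x -> rotation @ (x - translation).  ``rotation`` rows are the
    unit eigenvectors of the covariance matrix (orthonormal, det +1);
    ``translation`` is the cloud centroid in the parent frame (mm).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.translation) @ self.rotation.T

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation + self.translation


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Replace all points in each occupied voxel by their centroid.

    The grid is anchored on the fixed lattice ``floor(min / size) * size`` so
    that a second pass with the same voxel size is a no-op (idempotent).
    Labels are dropped (a centroid may mix labels).
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = cloud.points
    if len(pts) == 0:
        return PointCloud(pts.copy(), source_path=cloud.source_path)
    origin = np.floor(pts.min(axis=0) / voxel_size) * voxel_size
    idx = np.floor((pts - origin) / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, pts)
    centroids = sums / counts[:, None]
    return PointCloud(centroids, source_path=cloud.source_path)


def remove_outliers(cloud: PointCloud, k_neighbors: int = 20, std_ratio: float = 2.0) -> PointCloud:
    """Statistical outlier removal.

    A point is dropped when its mean distance to its ``k_neighbors`` nearest
    neighbours exceeds (global mean + ``std_ratio`` * global std) of that
    statistic.  Requires more than ``k_neighbors`` points.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    pts = cloud.points
    if len(pts) <= k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} points for neighbourhood "
            f"statistics, got {len(pts)}"
        )
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # drop self-distance
    cutoff = mean_d.mean() + std_ratio * mean_d.std()
    keep = np.flatnonzero(mean_d <= cutoff)
    return cloud.select(keep)


def _principal_frame(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and row-eigenvector rotation (desc. variance, sign-fixed, det +1)."""
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate covariance (rank < 2): points are collinear")
    axes = evecs[:, order].T  # rows e1, e2, e3
    # deterministic sign: largest-magnitude component of e1, e2 positive;
    # e3 completes a right-handed frame (det +1 takes precedence over its sign)
    for i in range(2):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return centroid, axes


def pca_align(cloud: PointCloud) -> tuple[PointCloud, RigidTransform]:
    """Translate the cloud to its centroid and rotate into its principal axes.

    Returns the aligned cloud (centroid at origin; X carries the largest
    covariance eigenvalue, then Y, then Z) and the rigid transform that maps
    parent coordinates into the aligned frame.
    """
    pts = cloud.points
    if len(pts) < 4:
        raise ValueError("pca_align needs at least 4 points")
    centroid, axes = _principal_frame(pts)
    transform = RigidTransform(rotation=axes, translation=centroid)
    aligned = PointCloud(transform.apply(pts), labels=None if cloud.labels is None else cloud.labels.copy(),
                         source_path=cloud.source_path)
    return aligned, transform
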