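"""Ventral-sulcus traits from cross-sections along the grain's length.

The aligned grain is cut into nine thin slabs spaced 0.4 mm apart and
centred on the grain centre; each slab's points are projected along X to
a 2D (y, z) profile.  The profile with the largest convex-hull area is
measured: the two farthest hull vertices are the sulcus edge points, a
RANSAC circle fit marks the profile point nearest the circle centre as
the crease's deepest point, and the sulcus depth D is the perpendicular
distance from that point to the edge-point chord.  Slice perimeter C_c
and area S_c come from the polar-angle-ordered profile polygon, and the
sulcus cross-section area S_s is the convex-hull area minus S_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .geometry import AlignedGrain

__all__ = [
    "SliceProfile",
    "CircleModel",
    "slice_grain",
    "select_max_hull_slice",
    "sulcus_edge_points",
    "fit_sulcus_circle",
    "sulcus_depth",
    "slice_measures",
    "measure_profile",
]


@dataclass
class SliceProfile:
    """One cross-section slab projected to the (y, z) plane.

    Measurement fields are ``None`` until filled by :func:`measure_profile`.
    """

    points2d: np.ndarray
    slab_center_x: float
    valid: bool = True
    hull: Optional[np.ndarray] = None          # hull vertex cycle, (m, 2)
    hull_area: Optional[float] = None
    edge_points: Optional[np.ndarray] = None   # (2, 2)
    deepest_point: Optional[np.ndarray] = None
    depth: Optional[float] = None              # D, mm
    perimeter: Optional[float] = None          # C_c, mm
    area: Optional[float] = None               # S_c, mm^2
    sulcus_area: Optional[float] = None        # S_s, mm^2

    def __post_init__(self) -> None:
        self.points2d = np.asarray(self.points2d, dtype=np.float64).reshape(-1, 2)


@dataclass
class CircleModel:
    """Circle (center, radius) with the RANSAC inlier set."""

    center: np.ndarray
    radius: float
    inlier_indices: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(2)
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")
        self.inlier_indices = np.asarray(self.inlier_indices, dtype=np.int64)


def slice_grain(
    grain: AlignedGrain,
    n_slices: int = 9,
    interval: float = 0.4,
    slab_thickness: float = 0.4,
) -> list[SliceProfile]:
    """Cut ``n_slices`` slabs along X, centred on the grain centre.

    Slab centres sit at x = k * interval for k = -(n-1)/2 ... (n-1)/2; each
    profile holds the (y, z) coordinates of points within +/- slab_thickness/2
    of its centre.  A slab with fewer than 3 points is flagged invalid.
    """
    pts = grain.cloud.points
    length = pts[:, 0].max() - pts[:, 0].min()
    extent = (n_slices - 1) * interval
    if length <= extent:
        raise ValueError(
            f"grain too short for slicing: length {length:.2f} mm <= slicing extent {extent:.2f} mm"
        )
    half = (n_slices - 1) // 2
    offsets = (np.arange(n_slices) - half) * interval
    if n_slices % 2 == 0:  # even counts straddle the centre symmetrically
        offsets = offsets + interval / 2.0
    profiles = []
    for cx in offsets:
        mask = np.abs(pts[:, 0] - cx) <= slab_thickness / 2.0
        pts2d = pts[mask][:, 1:3]
        profiles.append(SliceProfile(points2d=pts2d, slab_center_x=float(cx), valid=len(pts2d) >= 3))
    return profiles


def _hull(profile: SliceProfile) -> tuple[np.ndarray, float]:
    try:
        hull = ConvexHull(profile.points2d)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) slice profile") from exc
    return profile.points2d[hull.vertices], float(hull.volume)  # 2D: volume == area


def select_max_hull_slice(profiles: list[SliceProfile]) -> SliceProfile:
    """The valid profile with the largest convex-hull area.

    Ties break toward the smallest |slab centre| (the mid-grain slice).
    """
    best = None
    for prof in profiles:
        if not prof.valid:
            continue
        if prof.hull_area is None:
            prof.hull, prof.hull_area = _hull(prof)
        key = (-prof.hull_area, abs(prof.slab_center_x))
        if best is None or key < best[0]:
            best = (key, prof)
    if best is None:
        raise ValueError("no valid slice profiles")
    return best[1]


def sulcus_edge_points(profile: SliceProfile) -> tuple[np.ndarray, np.ndarray]:
    """The pair of hull vertices with maximal separation (the edge chord).

    All-pairs search over the hull vertices (cheap: hulls are small); ties
    break lexicographically for determinism.
    """
    if profile.hull is None:
        profile.hull, profile.hull_area = _hull(profile)
    hull = profile.hull
    uniq = np.unique(hull, axis=0)
    if len(uniq) < 2:
        raise ValueError("degenerate hull: fewer than 2 distinct points")
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    pairs = np.argwhere(d2 >= d2.max() - 1e-12)
    candidates = []
    for i, j in pairs:
        p, q = hull[i], hull[j]
        a, b = (p, q) if tuple(p) <= tuple(q) else (q, p)
        candidates.append((tuple(a), tuple(b)))
    a, b = min(candidates)
    return np.array(a), np.array(b)


def _circumcircles(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized circumcircle of point triples; returns (center, radius, ok)."""
    ax, ay = p1[:, 0], p1[:, 1]
    bx, by = p2[:, 0], p2[:, 1]
    cx, cy = p3[:, 0], p3[:, 1]
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ok = np.abs(d) > 1e-12
    d = np.where(ok, d, 1.0)
    a2, b2, c2 = ax**2 + ay**2, bx**2 + by**2, cx**2 + cy**2
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    center = np.column_stack([ux, uy])
    radius = np.linalg.norm(center - p1, axis=1)
    return center, radius, ok


def _kasa_fit(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle fit."""
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    radius = float(np.sqrt(max(sol[2] + center @ center, 0.0)))
    return center, radius


def fit_sulcus_circle(
    profile: SliceProfile,
    threshold: float = 0.3,
    iterations: int = 500,
    seed: int = 0,
    min_inlier_fraction: float = 0.25,
) -> CircleModel:
    """RANSAC circle over 3-point hypotheses, least-squares refit on inliers.

    Deterministic for a fixed seed.  Raises on collinear input or when no
    hypothesis reaches ``min_inlier_fraction`` of the points.
    """
    pts = profile.points2d
    n = len(pts)
    if n < 3:
        raise ValueError("circle fitting needs at least 3 points")
    rng = np.random.default_rng(seed)
    idx = np.array([rng.choice(n, size=3, replace=False) for _ in range(iterations)])
    centers, radii, ok = _circumcircles(pts[idx[:, 0]], pts[idx[:, 1]], pts[idx[:, 2]])
    if not ok.any():
        raise ValueError("all sampled triples were collinear")
    # residual matrix: | |p - c| - r | for each hypothesis x point
    d = np.linalg.norm(pts[None, :, :] - centers[:, None, :], axis=2)
    resid = np.abs(d - radii[:, None])
    counts = np.where(ok, (resid <= threshold).sum(axis=1), -1)
    best = int(np.argmax(counts))
    if counts[best] < max(3, min_inlier_fraction * n):
        raise ValueError(
            f"no circle hypothesis reached the minimum inlier fraction "
            f"({counts[best]}/{n} < {min_inlier_fraction})"
        )
    inliers = np.flatnonzero(resid[best] <= threshold)
    center, radius = _kasa_fit(pts[inliers])
    if radius <= 0:
        center, radius = centers[best], float(radii[best])
    resid_ref = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
    inliers = np.flatnonzero(resid_ref <= threshold)
    return CircleModel(center=center, radius=radius, inlier_indices=inliers)


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    norm = np.linalg.norm(ab)
    if norm < 1e-12:
        raise ValueError("edge points coincide: sulcus chord is undefined")
    ap = p - a
    return float(abs(ab[0] * ap[1] - ab[1] * ap[0]) / norm)


def sulcus_depth(profile: SliceProfile, circle: Optional[CircleModel] = None, **ransac_kwargs) -> float:
    """Depth D (mm): deepest point to the edge-point chord.

    The deepest point is the profile point nearest the fitted circle's
    centre; D is its perpendicular distance to the line through the two
    sulcus edge points.
    """
    if circle is None:
        circle = fit_sulcus_circle(profile, **ransac_kwargs)
    p1, p2 = sulcus_edge_points(profile)
    pts = profile.points2d
    deepest = pts[np.argmin(np.linalg.norm(pts - circle.center, axis=1))]
    profile.deepest_point = deepest
    profile.edge_points = np.vstack([p1, p2])
    depth = _point_line_distance(deepest, p1, p2)
    profile.depth = depth
    return depth


def slice_measures(profile: SliceProfile) -> tuple[float, float, float]:
    """Slice perimeter C_c, slice area S_c and sulcus area S_s.

    Points are ordered by polar angle about the profile centroid (the
    profile is assumed star-shaped about it; violations only warn).  C_c is
    the closed cycle length; S_c the signed centroid-fan (shoelace) area, so
    concave crease wedges subtract correctly; S_s = hull area - S_c.
    """
    pts = profile.points2d
    if len(pts) < 3:
        raise ValueError("slice measures need at least 3 points")
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]), kind="stable")
    poly = pts[order]
    closed = np.vstack([poly, poly[:1]])
    perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    x, y = poly[:, 0], poly[:, 1]
    area_signed = 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    area = abs(area_signed)
    if area < 1e-12:
        raise ValueError("degenerate (zero-area) slice profile")
    if profile.hull_area is None:
        profile.hull, profile.hull_area = _hull(profile)
    sulcus_area = profile.hull_area - area
    if sulcus_area < -1e-6 * max(profile.hull_area, 1.0):
        warnings.warn(
            "fan area exceeds hull area: profile may not be star-shaped about its centroid",
            stacklevel=2,
        )
    profile.perimeter, profile.area, profile.sulcus_area = perimeter, area, sulcus_area
    return perimeter, area, sulcus_area


def measure_profile(
    profile: SliceProfile,
    circle_threshold: float = 0.3,
    circle_iterations: int = 500,
    circle_seed: int = 0,
) -> SliceProfile:
    """Fill every measurement field of a profile (hull, depth, C_c, S_c, S_s)."""
    if not profile.valid:
        raise ValueError("cannot measure an invalid (under-populated) profile")
    profile.hull, profile.hull_area = _hull(profile)
    circle = fit_sulcus_circle(
        profile, threshold=circle_threshold, iterations=circle_iterations, seed=circle_seed
    )
    sulcus_depth(profile, circle=circle)
    slice_measures(profile)
    return profile
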