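"""Per-grain morphometry: bounding-box dimensions, surface mesh, area,
volume, axis projections, roundness and sphericity.

A segmented grain is first rotated into its principal frame (X = major
axis, origin at the geometric centre); length/width/thickness are then
the axis-aligned extents.  The surface is triangulated, its area is the
sum of per-triangle Heron areas, and the enclosed volume is the signed
tetrahedron (divergence-theorem) sum over the closed oriented mesh.
2D outlines of the three axis projections supply section areas,
perimeters and roundness (4*pi*S/C^2); sphericity compares the surface
area with that of the equal-volume sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .cloud_io import PointCloud, TriangleMesh
from .preprocess import RigidTransform, pca_align

__all__ = [
    "AlignedGrain",
    "Outline2D",
    "align_grain",
    "obb_dimensions",
    "reconstruct_surface",
    "surface_area",
    "enclosed_volume",
    "projected_outline",
    "roundness",
    "sphericity",
    "fill_holes",
    "orient_faces",
    "OpenMeshError",
]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2, "x": 0, "y": 1, "z": 2}


class OpenMeshError(ValueError):
    """Mesh has boundary edges after hole filling."""


@dataclass
class AlignedGrain:
    """A single grain in its local principal frame.

    ``cloud`` has its centroid at the origin and axes ordered by descending
    covariance eigenvalue (X = major axis); ``transform`` maps parent-frame
    coordinates into this frame.
    """

    cloud: PointCloud
    transform: RigidTransform


@dataclass
class Outline2D:
    """Area (mm^2) and perimeter (mm) of one axis projection of a grain."""

    area: float
    perimeter: float
    axis: str


def align_grain(cloud: PointCloud) -> AlignedGrain:
    """Rotate/translate a grain segment into its principal frame."""
    aligned, transform = pca_align(cloud)
    return AlignedGrain(cloud=aligned, transform=transform)


def obb_dimensions(grain: AlignedGrain) -> tuple[float, float, float]:
    """Length, width, thickness (mm): axis-aligned extents in the grain frame.

    The oriented bounding box of the raw segment is the axis-aligned box of
    the PCA-aligned cloud, so l >= w >= h for ellipsoid-like grains.
    """
    pts = grain.cloud.points
    if len(pts) < 4:
        raise ValueError("empty or degenerate segment")
    extents = pts.max(axis=0) - pts.min(axis=0)
    return float(extents[0]), float(extents[1]), float(extents[2])


def _star_triangulation(pts: np.ndarray, c: np.ndarray) -> TriangleMesh:
    rel = pts - c
    radii = np.linalg.norm(rel, axis=1)
    if radii.min() < 1e-12:
        keep = radii > 1e-12
        pts, rel, radii = pts[keep], rel[keep], radii[keep]
    dirs = rel / radii[:, None]
    try:
        hull = ConvexHull(dirs, qhull_options="QJ")  # joggle collapses duplicate dirs
    except QhullError as exc:  # pragma: no cover - degenerate input
        raise ValueError("could not triangulate surface (degenerate directions)") from exc
    faces = hull.simplices.astype(np.int64)
    # orient every face outward (normal away from the centre)
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    outward = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - c)
    flip = outward < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriangleMesh(vertices=pts, faces=faces)


def reconstruct_surface(cloud: PointCloud, center: np.ndarray | None = None) -> TriangleMesh:
    """Triangulate a closed grain surface from its point sample.

    Grains are star-shaped about interior points on their minor axis, so
    the surface is triangulated by projecting every point radially onto the
    unit sphere around a centre and taking the convex hull of the
    directions; the hull connectivity is applied to the original points.
    The result is watertight and consistently outward-oriented by
    construction, and every mesh vertex is an input point.

    With ``center=None`` several candidate centres along the cloud's third
    coordinate axis are tried and the triangulation with the smallest total
    area is kept: a centre that fails to see part of the surface radially
    (e.g. into the ventral crease) folds the triangulation, which only ever
    inflates the area, so the minimum identifies the best star centre.  For
    convex clouds all candidates are equivalent.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    if len(pts) < 4:
        raise ValueError("surface reconstruction needs at least 4 points")
    centroid = pts.mean(axis=0)
    if center is not None:
        return _star_triangulation(pts, np.asarray(center, dtype=np.float64))
    half_range = (pts[:, 2].max() - pts[:, 2].min()) / 2.0
    best = None
    for frac in (0.0, 0.3, -0.3):
        c = centroid + np.array([0.0, 0.0, frac * half_range])
        mesh = _star_triangulation(pts, c)
        area = surface_area(mesh)
        if best is None or area < best[0]:
            best = (area, mesh)
    return best[1]


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area (mm^2) as the sum of per-triangle Heron areas.

    For each triangle with side lengths a, b, c and semi-perimeter p the
    area is sqrt(p(p-a)(p-b)(p-c)); radicands driven negative by rounding on
    degenerate triangles clamp to zero.
    """
    if mesh.faces.size == 0:
        return 0.0
    tri = mesh.triangles
    a = np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1)
    b = np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1)
    c = np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1)
    p = (a + b + c) / 2.0
    radicand = p * (p - a) * (p - b) * (p - c)
    return float(np.sum(np.sqrt(np.clip(radicand, 0.0, None))))


def _edge_face_table(faces: np.ndarray) -> dict[tuple[int, int], list[tuple[int, bool]]]:
    """Map undirected edge -> [(face index, traversed-as-sorted?), ...]."""
    table: dict[tuple[int, int], list[tuple[int, bool]]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            table.setdefault(key, []).append((fi, u < v))
    return table


def orient_faces(mesh: TriangleMesh) -> TriangleMesh:
    """Flip faces until adjacent faces traverse shared edges in opposite order.

    Breadth-first over the face adjacency; each connected component becomes
    internally consistent (globally the mesh may still be inside-out, which
    the volume step absorbs with an absolute value).
    """
    faces = mesh.faces.copy()
    table = _edge_face_table(faces)
    n_faces = len(faces)
    visited = np.zeros(n_faces, dtype=bool)
    flipped = np.zeros(n_faces, dtype=bool)
    for start in range(n_faces):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        while stack:
            fi = stack.pop()
            a, b, c = faces[fi]
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                for fj, _ in table[key]:
                    if fj == fi or visited[fj]:
                        continue
                    fa, fb, fc = faces[fj]
                    same_dir = (u, v) in ((fa, fb), (fb, fc), (fc, fa))
                    if same_dir:  # neighbour traverses the edge the same way -> flip it
                        faces[fj] = faces[fj][[0, 2, 1]]
                        flipped[fj] = True
                    visited[fj] = True
                    stack.append(fj)
    return TriangleMesh(vertices=mesh.vertices, faces=faces)


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    table = _edge_face_table(faces)
    boundary = [e for e, fs in table.items() if len(fs) == 1]
    if not boundary:
        return []
    succ: dict[int, list[int]] = {}
    for u, v in boundary:
        succ.setdefault(u, []).append(v)
        succ.setdefault(v, []).append(u)
    loops = []
    unused = {tuple(sorted(e)) for e in boundary}
    while unused:
        u0, v0 = next(iter(unused))
        loop = [u0, v0]
        unused.discard((u0, v0))
        while True:
            cur, prev = loop[-1], loop[-2]
            nxts = [w for w in succ.get(cur, []) if tuple(sorted((cur, w))) in unused]
            if not nxts:
                break
            nxt = nxts[0]
            unused.discard(tuple(sorted((cur, nxt))))
            if nxt == loop[0]:
                break
            loop.append(nxt)
        loops.append(loop)
    return loops


def fill_holes(mesh: TriangleMesh, max_edges: int = 30) -> TriangleMesh:
    """Fan-fill boundary loops with at most ``max_edges`` edges.

    Larger holes are left open (the caller decides whether that is an
    error); the scanner pipeline assumes an essentially closed scan.
    """
    loops = _boundary_loops(mesh.faces)
    if not loops:
        return mesh
    new_faces = [mesh.faces]
    for loop in loops:
        if len(loop) > max_edges or len(loop) < 3:
            continue
        anchor = loop[0]
        fan = [(anchor, loop[i], loop[i + 1]) for i in range(1, len(loop) - 1)]
        new_faces.append(np.array(fan, dtype=np.int64))
    return TriangleMesh(vertices=mesh.vertices, faces=np.vstack(new_faces))


def enclosed_volume(mesh: TriangleMesh, hole_fill_max_edges: int = 30) -> float:
    """Volume (mm^3) enclosed by a closed mesh, by signed tetrahedra.

    Faces are re-oriented for consistency and small boundary loops are
    fan-filled first; a mesh that still has boundary edges raises
    :class:`OpenMeshError` naming the open-edge count.  The signed sum of
    tetrahedron volumes (face, origin) equals the enclosed volume for any
    consistently oriented closed mesh; the absolute value makes the result
    independent of global orientation.
    """
    if mesh.faces.size == 0:
        raise ValueError("empty mesh has no volume")
    mesh = fill_holes(mesh, max_edges=hole_fill_max_edges)
    table = _edge_face_table(mesh.faces)
    open_edges = sum(1 for fs in table.values() if len(fs) != 2)
    if open_edges:
        raise OpenMeshError(f"mesh is not closed: {open_edges} open edges after hole filling")
    mesh = orient_faces(mesh)
    tri = mesh.triangles
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def _alpha_complex(pts2d: np.ndarray, edge_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay triangles with all edges below a locally adaptive limit.

    Projected grain clouds mix very different densities (silhouette edges
    collect points from the whole depth range, face interiors do not), so a
    single global length cut-off fails.  Each point gets a local scale (its
    8th-nearest-neighbour distance) and an edge survives when it is at most
    ``edge_factor`` times the larger of its endpoints' scales; long
    convex-hull bridges across true concavities still exceed the limit.
    Returns (triangles, boundary edges used by exactly one kept triangle).
    """
    tri = Delaunay(pts2d)
    k = min(8, len(pts2d) - 1)
    scale = cKDTree(pts2d).query(pts2d, k=k + 1)[0][:, -1]
    simplices = tri.simplices
    keep = np.ones(len(simplices), dtype=bool)
    p = pts2d[simplices]
    for i, j in ((0, 1), (1, 2), (2, 0)):
        length = np.linalg.norm(p[:, i] - p[:, j], axis=1)
        limit = edge_factor * np.maximum(scale[simplices[:, i]], scale[simplices[:, j]])
        keep &= length <= limit
    kept = simplices[keep]
    if kept.size == 0:
        raise ValueError("no triangles survive the edge-length filter; sample too sparse")
    edges = np.vstack([kept[:, [0, 1]], kept[:, [1, 2]], kept[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return kept, uniq[counts == 1]


def projected_outline(grain: AlignedGrain, axis: str, edge_factor: float = 2.0) -> Outline2D:
    """Area and perimeter of the grain's projection along one local axis.

    The named coordinate is dropped, the planar points are triangulated
    (Delaunay restricted to short edges, so concavities are respected), the
    area is the sum of triangle areas and the perimeter the summed length
    of edges belonging to exactly one triangle.
    """
    ax = _AXIS_INDEX.get(axis if isinstance(axis, str) else "XYZ"[axis])
    if ax is None:
        raise ValueError(f"axis must be one of X, Y, Z; got {axis!r}")
    pts = grain.cloud.points
    if len(pts) < 3:
        raise ValueError("projection needs at least 3 points")
    keep_cols = [i for i in range(3) if i != ax]
    pts2d = pts[:, keep_cols]
    try:
        triangles, boundary = _alpha_complex(pts2d, edge_factor)
    except QhullError as exc:
        raise ValueError("projected points are collinear") from exc
    p = pts2d[triangles]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    area = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]).sum()
    seg = pts2d[boundary]
    perimeter = np.linalg.norm(seg[:, 0] - seg[:, 1], axis=1).sum()
    return Outline2D(area=float(area), perimeter=float(perimeter), axis="XYZ"[ax])


def roundness(outline: Outline2D) -> float:
    """Isoperimetric shape index c = 4*pi*S / C^2 (1 for a circle)."""
    if outline.perimeter <= 0:
        raise ValueError("roundness needs a positive perimeter")
    return float(4.0 * np.pi * outline.area / outline.perimeter**2)


def sphericity(volume: float, area: float) -> float:
    """Sphericity E = S_e / S_a with S_e the equal-volume sphere's area.

    E = pi^(1/3) (6V)^(2/3) / S_a; 1 for a sphere, below 1 otherwise.
    """
    if volume <= 0 or area <= 0:
        raise ValueError("sphericity needs positive volume and surface area")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
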