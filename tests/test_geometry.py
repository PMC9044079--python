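"""Morphometry: bounding box, surface mesh, area, volume, projections,
roundness and sphericity, with independent analytic and library oracles."""

import numpy as np
import pytest

from grain3d.cloud_io import PointCloud, TriangleMesh
from grain3d.geometry import (
    OpenMeshError,
    align_grain,
    enclosed_volume,
    obb_dimensions,
    projected_outline,
    reconstruct_surface,
    roundness,
    sphericity,
    surface_area,
    Outline2D,
)

from conftest import random_rotation, sphere_cloud


def cube_mesh():
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)

    def quad(a, b, c, d):
        return [(a, b, c), (a, c, d)]

    faces = (quad(0, 1, 3, 2) + quad(4, 6, 7, 5) + quad(0, 4, 5, 1)
             + quad(2, 3, 7, 6) + quad(0, 2, 6, 4) + quad(1, 5, 7, 3))
    return TriangleMesh(v, np.array(faces))


def box_sample(l=6.0, w=3.0, h=2.8, n=4000, seed=0, noise=0.005):
    """Area-weighted sample of a box surface with scanner-scale jitter
    (exactly coplanar faces would degenerate the projected Delaunay)."""
    g = np.random.default_rng(seed)
    dims = np.array([l, w, h])
    areas = np.array([w * h, w * h, l * h, l * h, l * w, l * w], float)
    face = g.choice(6, size=n, p=areas / areas.sum())
    uv = g.uniform(0, 1, (n, 2))
    pts = np.empty((n, 3))
    for f in range(6):
        m = face == f
        axis = f // 2
        side = f % 2
        others = [i for i in range(3) if i != axis]
        pts[m, axis] = side * dims[axis]
        pts[m, others[0]] = uv[m, 0] * dims[others[0]]
        pts[m, others[1]] = uv[m, 1] * dims[others[1]]
    return pts - dims / 2 + g.normal(0, noise, (n, 3))


class TestSurfaceArea:
    def test_heron_equals_cross_product_on_random_triangles(self, rng):
        tri = rng.uniform(-10, 10, (10_000, 3, 3))
        heron = np.array(
            [surface_area(TriangleMesh(t, np.array([[0, 1, 2]]))) for t in tri[:100]]
        )
        cross = 0.5 * np.linalg.norm(
            np.cross(tri[:100, 1] - tri[:100, 0], tri[:100, 2] - tri[:100, 0]), axis=1
        )
        assert np.abs(heron - cross).max() <= 1e-9 * np.abs(cross).max()
        # the remaining triangles in one vectorized comparison through one mesh
        verts = tri.reshape(-1, 3)
        faces = np.arange(len(verts)).reshape(-1, 3)
        total_cross = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum()
        assert surface_area(TriangleMesh(verts, faces)) == pytest.approx(total_cross, rel=1e-9)

    def test_known_shapes(self):
        t345 = TriangleMesh(np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0.]]), np.array([[0, 1, 2]]))
        assert surface_area(t345) == pytest.approx(6.0, abs=1e-12)
        assert surface_area(cube_mesh()) == pytest.approx(6.0, rel=1e-12)
        assert surface_area(TriangleMesh(np.empty((0, 3)), np.empty((0, 3), int))) == 0.0

    def test_matches_trimesh(self):
        import trimesh

        mesh = reconstruct_surface(PointCloud(sphere_cloud(1500, 2.5, seed=1)))
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        assert surface_area(mesh) == pytest.approx(tm.area, rel=1e-9)


class TestEnclosedVolume:
    def test_cube_under_orientation_abuse(self, rng):
        mesh = cube_mesh()
        assert enclosed_volume(mesh) == pytest.approx(1.0, rel=1e-12)
        scrambled = mesh.faces.copy()
        flip = rng.random(len(scrambled)) < 0.5
        scrambled[flip] = scrambled[flip][:, [0, 2, 1]]
        assert enclosed_volume(TriangleMesh(mesh.vertices, scrambled)) == pytest.approx(1.0, rel=1e-12)
        mirrored = mesh.faces[:, [0, 2, 1]]
        assert enclosed_volume(TriangleMesh(mesh.vertices, mirrored)) == pytest.approx(1.0, rel=1e-12)

    def test_small_hole_filled_large_hole_raises(self):
        mesh = cube_mesh()
        open_mesh = TriangleMesh(mesh.vertices, mesh.faces[:-2])  # one quad hole
        assert enclosed_volume(open_mesh) == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(OpenMeshError, match="open edges"):
            enclosed_volume(open_mesh, hole_fill_max_edges=2)

    def test_sphere_volume_and_area(self):
        mesh = reconstruct_surface(PointCloud(sphere_cloud(5000, 3.0, seed=2)))
        assert enclosed_volume(mesh) == pytest.approx(4 / 3 * np.pi * 27, rel=0.05)
        assert surface_area(mesh) == pytest.approx(4 * np.pi * 9, rel=0.05)

    def test_volume_against_monte_carlo(self):
        """Signed-tetrahedron volume vs point-in-solid Monte Carlo."""
        ell = sphere_cloud(4000, 1.0, seed=3) * np.array([4.0, 2.0, 1.5])
        mesh = reconstruct_surface(PointCloud(ell))
        g = np.random.default_rng(4)
        box = g.uniform(-1, 1, (200_000, 3)) * np.array([4, 2, 1.5])
        inside = ((box / np.array([4, 2, 1.5])) ** 2).sum(axis=1) < 1.0
        mc = inside.mean() * 8 * 4 * 2 * 1.5
        assert enclosed_volume(mesh) == pytest.approx(mc, rel=0.02)

    def test_matches_trimesh(self):
        import trimesh

        mesh = reconstruct_surface(PointCloud(sphere_cloud(1500, 2.5, seed=5)))
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        assert enclosed_volume(mesh) == pytest.approx(abs(tm.volume), rel=1e-9)


class TestReconstruction:
    def test_vertices_are_input_points(self):
        pts = sphere_cloud(500, 2.0, seed=6)
        mesh = reconstruct_surface(PointCloud(pts))
        as_set = {tuple(p) for p in pts}
        assert all(tuple(v) in as_set for v in mesh.vertices)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            reconstruct_surface(PointCloud(np.array([[0, 0, 0], [1, 0, 0.]])))


class TestObbDimensions:
    def test_recovers_rotated_box(self):
        # w and h must differ clearly: PCA cannot separate near-equal
        # second moments, so a 3 x 2.8 section wobbles by several degrees
        pts = box_sample(6, 3, 2.2, n=60000, seed=7, noise=0.002) @ random_rotation(seed=8).T
        grain = align_grain(PointCloud(pts))
        l, w, h = obb_dimensions(grain)
        assert l == pytest.approx(6.0, rel=0.02)
        assert w == pytest.approx(3.0, rel=0.02)
        assert h == pytest.approx(2.2, rel=0.02)

    def test_rigid_invariance(self):
        pts = box_sample(5, 2.5, 2.0, seed=9)
        d1 = obb_dimensions(align_grain(PointCloud(pts)))
        moved = pts @ random_rotation(seed=10).T + np.array([7.0, -3.0, 2.0])
        d2 = obb_dimensions(align_grain(PointCloud(moved)))
        assert np.abs(np.array(d1) - np.array(d2)).max() < 1e-6


class TestProjectedOutline:
    def test_rectangle_projection_area_and_perimeter(self):
        # two parallel faces of a box: their Z-projection is a 6 x 3 rectangle
        g = np.random.default_rng(11)
        uv = g.uniform(0, 1, (8000, 2)) * np.array([6.0, 3.0]) - np.array([3.0, 1.5])
        # plate separation well below the rectangle's short side so the
        # principal frame keeps Z as the projection axis
        z = np.where(g.random(8000) < 0.5, -0.5, 0.5) + g.normal(0, 0.005, 8000)
        pts = np.column_stack([uv, z])
        grain = align_grain(PointCloud(pts))
        out = projected_outline(grain, "Z")
        assert out.area == pytest.approx(6 * 3, rel=0.03)
        assert out.perimeter == pytest.approx(2 * (6 + 3), rel=0.03)

    def test_unit_square_sample(self, rng):
        pts2 = rng.uniform(0, 1, (4000, 2))
        pts = np.column_stack([pts2, rng.normal(0, 1e-4, 4000)])
        grain = align_grain(PointCloud(pts))
        out = projected_outline(grain, "Z")
        assert out.area == pytest.approx(1.0, rel=0.03)
        assert out.perimeter == pytest.approx(4.0, rel=0.03)

    def test_collinear_projection_raises(self):
        from grain3d.geometry import AlignedGrain
        from grain3d.preprocess import RigidTransform

        line = np.stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50), np.zeros(50)], axis=1)
        grain = AlignedGrain(cloud=PointCloud(line),
                             transform=RigidTransform(np.eye(3), np.zeros(3)))
        with pytest.raises(ValueError):
            projected_outline(grain, "X")


class TestShapeIndices:
    def test_roundness_closed_forms(self):
        circle = Outline2D(area=4 * np.pi, perimeter=4 * np.pi, axis="X")
        assert roundness(circle) == pytest.approx(1.0, rel=1e-12)
        square = Outline2D(area=4.0, perimeter=8.0, axis="X")
        assert roundness(square) == pytest.approx(np.pi / 4, rel=1e-12)
        with pytest.raises(ValueError):
            roundness(Outline2D(area=1.0, perimeter=0.0, axis="X"))

    def test_isoperimetric_bound_on_measured_outlines(self, default_grain_traits):
        record, _, _ = default_grain_traits
        for key in ("c_yz", "c_xz", "c_xy"):
            assert 0 < record[key] <= 1.02

    def test_sphericity_closed_forms(self):
        assert sphericity(4 / 3 * np.pi, 4 * np.pi) == pytest.approx(1.0, rel=1e-12)
        assert sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=2e-5)
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)

    def test_sphericity_decreases_with_elongation(self):
        values = []
        for ratio in (1.0, 1.5, 2.5, 4.0):
            # fixed-volume ellipsoid, increasingly elongated
            a = ratio ** (2 / 3)
            b = c = ratio ** (-1 / 3)
            pts = sphere_cloud(4000, 1.0, seed=12) * np.array([a, b, c]) * 3
            mesh = reconstruct_surface(PointCloud(pts))
            values.append(sphericity(enclosed_volume(mesh), surface_area(mesh)))
        assert values[0] > values[1] > values[2] > values[3]
        assert values[0] == pytest.approx(1.0, abs=0.03)


def test_traits_rigid_invariance(default_grain):
    """l, w, h, V, S and outline measures are unchanged by rigid motion."""
    from grain3d.pipeline import extract_grain_traits

    cloud, _ = default_grain
    rec1, _ = extract_grain_traits(cloud)
    moved = PointCloud(cloud.points @ random_rotation(seed=13).T + np.array([11.0, -4.0, 6.0]))
    rec2, _ = extract_grain_traits(moved)
    for key in ("l", "w", "h", "V", "S", "D", "S_yz", "S_xz", "S_xy", "C_c", "S_c", "E"):
        assert rec2[key] == pytest.approx(rec1[key], rel=1e-6), key
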