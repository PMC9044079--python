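"""Ventral-sulcus slicing, circle fitting and depth/area measures."""

import itertools

import numpy as np
import pytest

from grain3d.cloud_io import PointCloud
from grain3d.geometry import align_grain
from grain3d.sulcus import (
    SliceProfile,
    fit_sulcus_circle,
    measure_profile,
    select_max_hull_slice,
    slice_grain,
    slice_measures,
    sulcus_depth,
    sulcus_edge_points,
)
from grain3d.synthetic import GrainParams, make_grain


def circle_profile(n=360, r=2.0, center=(0.0, 0.0), noise=0.0, seed=0):
    g = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    if noise:
        pts += g.normal(0, noise, pts.shape)
    return SliceProfile(points2d=pts, slab_center_x=0.0)


def v_profile(n=240):
    """Notched profile with lips at (+-1, 0) and bottom vertex (0, -0.5).

    The top is a unit-radius arc about the origin; the flanks are arc-like
    spirals whose radius falls monotonically from 1 to 0.5, so the profile
    point nearest the fitted circle's centre is the bottom vertex and the
    analytic depth to the lip chord is exactly 0.5.
    """
    t = np.linspace(0, np.pi, n // 2)
    top = np.column_stack([np.cos(t), np.sin(t)])
    th = np.linspace(np.pi, 1.5 * np.pi, n // 4, endpoint=False)
    r = np.linspace(1.0, 0.5, n // 4, endpoint=False)
    left = np.column_stack([r * np.cos(th), r * np.sin(th)])
    right = left[1:] * np.array([-1.0, 1.0])
    pts = np.vstack([top, left, right, [[0.0, -0.5]]])
    return SliceProfile(points2d=pts, slab_center_x=0.0)


class TestSliceGrain:
    def test_default_slicing_yields_nine_centred_profiles(self, default_grain):
        cloud, _ = default_grain
        profiles = slice_grain(align_grain(cloud))
        assert len(profiles) == 9
        centers = [p.slab_center_x for p in profiles]
        assert centers == pytest.approx(list(np.arange(-4, 5) * 0.4))
        assert centers[4] == 0.0
        assert all(p.valid for p in profiles)

    def test_short_grain_raises(self):
        g = np.random.default_rng(0)
        pts = g.uniform(-1, 1, (500, 3)) * np.array([1.5, 1.0, 0.5])
        with pytest.raises(ValueError, match="too short"):
            slice_grain(align_grain(PointCloud(pts)))

    def test_profiles_project_to_yz(self, default_grain):
        cloud, _ = default_grain
        grain = align_grain(cloud)
        prof = slice_grain(grain)[4]
        slab = grain.cloud.points[np.abs(grain.cloud.points[:, 0]) <= 0.2]
        assert len(prof.points2d) == len(slab)


class TestSelectMaxHullSlice:
    def test_central_slice_of_ellipsoid_selected(self, smooth_grain):
        cloud, _ = smooth_grain
        profiles = slice_grain(align_grain(cloud))
        best = select_max_hull_slice(profiles)
        assert abs(best.slab_center_x) <= 0.4

    def test_single_profile_returned(self):
        prof = circle_profile()
        assert select_max_hull_slice([prof]) is prof

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            select_max_hull_slice([])


class TestEdgePoints:
    def test_triangle_hull_diameter(self):
        prof = SliceProfile(points2d=np.array([[-2, 0], [2, 0], [0, 1.0]]), slab_center_x=0.0)
        p1, p2 = sulcus_edge_points(prof)
        assert np.allclose(p1, [-2, 0]) and np.allclose(p2, [2, 0])

    def test_matches_all_pairs_brute_force(self, rng):
        pts = rng.uniform(-3, 3, (40, 2))
        prof = SliceProfile(points2d=pts, slab_center_x=0.0)
        p1, p2 = sulcus_edge_points(prof)
        best = max(
            itertools.combinations(pts.tolist(), 2),
            key=lambda ab: (np.array(ab[0]) - np.array(ab[1])) @ (np.array(ab[0]) - np.array(ab[1])),
        )
        d_best = np.linalg.norm(np.array(best[0]) - np.array(best[1]))
        assert np.linalg.norm(p1 - p2) == pytest.approx(d_best, rel=1e-12)

    def test_duplicate_points_raise(self):
        prof = SliceProfile(points2d=np.array([[1.0, 1.0]] * 5), slab_center_x=0.0)
        with pytest.raises(ValueError):
            sulcus_edge_points(prof)


class TestCircleFit:
    def test_exact_circle_recovered(self):
        prof = circle_profile(100, r=3.0, center=(1.0, 2.0))
        model = fit_sulcus_circle(prof)
        assert np.abs(model.center - [1, 2]).max() < 1e-6
        assert model.radius == pytest.approx(3.0, abs=1e-6)

    def test_robust_to_scattered_outliers(self):
        prof = circle_profile(100, r=3.0, center=(1.0, 2.0))
        g = np.random.default_rng(1)
        outliers = g.uniform(-3, 6, (25, 2))
        prof = SliceProfile(points2d=np.vstack([prof.points2d, outliers]), slab_center_x=0.0)
        model = fit_sulcus_circle(prof, threshold=0.05, seed=0)
        assert np.abs(model.center - [1, 2]).max() < 0.02

    def test_collinear_points_raise(self):
        prof = SliceProfile(points2d=np.column_stack([np.arange(5.0), np.arange(5.0)]),
                            slab_center_x=0.0)
        with pytest.raises(ValueError):
            fit_sulcus_circle(prof)

    def test_deterministic_given_seed(self):
        prof = circle_profile(80, noise=0.02, seed=2)
        m1 = fit_sulcus_circle(prof, seed=7)
        m2 = fit_sulcus_circle(prof, seed=7)
        assert np.array_equal(m1.center, m2.center)
        assert np.array_equal(m1.inlier_indices, m2.inlier_indices)

    def test_equals_exhaustive_search_on_tiny_input(self, rng):
        """RANSAC with many iterations matches brute force over all triples."""
        pts = circle_profile(9, r=2.0, noise=0.05, seed=3).points2d
        pts = np.vstack([pts, rng.uniform(-1, 1, (3, 2))])
        prof = SliceProfile(points2d=pts, slab_center_x=0.0)
        threshold = 0.1
        best_count = 0
        for i, j, k in itertools.combinations(range(len(pts)), 3):
            a, b, c = pts[i], pts[j], pts[k]
            d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
            if abs(d) < 1e-12:
                continue
            a2, b2, c2 = a @ a, b @ b, c @ c
            ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
            uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
            r = np.hypot(*(a - [ux, uy]))
            resid = np.abs(np.linalg.norm(pts - [ux, uy], axis=1) - r)
            best_count = max(best_count, int((resid <= threshold).sum()))
        model = fit_sulcus_circle(prof, threshold=threshold, iterations=2000, seed=0,
                                  min_inlier_fraction=0.0)
        assert len(model.inlier_indices) >= best_count - 1


class TestDepthAndMeasures:
    def test_v_profile_depth(self):
        # noise-free profile: circle threshold tightened to the data's scale
        prof = v_profile()
        depth = sulcus_depth(prof, threshold=0.05)
        assert depth == pytest.approx(0.5, rel=0.02)

    def test_depth_rigid_invariance(self):
        prof = v_profile()
        d1 = sulcus_depth(prof, threshold=0.05)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = SliceProfile(points2d=prof.points2d @ rot.T + [3.0, -1.0], slab_center_x=0.0)
        assert sulcus_depth(moved, threshold=0.05) == pytest.approx(d1, rel=1e-9)

    def test_circle_slice_measures(self):
        prof = circle_profile(360, r=2.0)
        c, s, ss = slice_measures(prof)
        assert c == pytest.approx(4 * np.pi, rel=0.005)
        assert s == pytest.approx(4 * np.pi, rel=0.005)
        assert abs(ss) < 0.01

    def test_square_corner_measures(self):
        prof = SliceProfile(points2d=np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]),
                            slab_center_x=0.0)
        c, s, ss = slice_measures(prof)
        assert c == pytest.approx(4.0, rel=1e-12)
        assert s == pytest.approx(1.0, rel=1e-12)
        assert ss == pytest.approx(0.0, abs=1e-9)

    def test_measures_rigid_invariance(self):
        prof = v_profile()
        c1, s1, ss1 = slice_measures(prof)
        theta = -1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = SliceProfile(points2d=prof.points2d @ rot.T + [-2.0, 5.0], slab_center_x=0.0)
        c2, s2, ss2 = slice_measures(moved)
        assert (c2, s2) == pytest.approx((c1, s1), rel=1e-9)
        assert ss2 == pytest.approx(ss1, abs=1e-9)

    def test_degenerate_profile_raises(self):
        prof = SliceProfile(points2d=np.zeros((5, 2)), slab_center_x=0.0)
        with pytest.raises(ValueError):
            slice_measures(prof)


class TestGeneratorRecovery:
    def test_planted_depth_recovered(self, default_grain, default_grain_traits):
        _, _, gt = default_grain_traits
        record, _, _ = default_grain_traits
        assert record["D"] == pytest.approx(gt.D, rel=0.10)

    def test_sulcus_area_positive_and_near_truth(self, default_grain_traits):
        record, _, gt = default_grain_traits
        assert record["S_s"] > 0
        assert record["S_s"] == pytest.approx(gt.sulcus_area, rel=0.25)

    def test_depth_monotone_in_groove_parameter(self):
        depths = []
        for d in (0.1, 0.3, 0.5, 0.7, 0.9):
            cloud, _ = make_grain(
                GrainParams(groove_depth=d, noise_sd=0.0, seed=11), gt_resolution=120
            )
            best = select_max_hull_slice(slice_grain(align_grain(cloud)))
            depths.append(sulcus_depth(best))
        assert all(b > a - 0.02 for a, b in zip(depths, depths[1:]))

    def test_no_groove_measures_near_zero_depth(self):
        """groove_depth = 0 carves the crease floor onto the width chord."""
        cloud, _ = make_grain(GrainParams(groove_depth=0.0, noise_sd=0.0, seed=12),
                              gt_resolution=120)
        best = select_max_hull_slice(slice_grain(align_grain(cloud)))
        assert sulcus_depth(best) <= 0.05
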