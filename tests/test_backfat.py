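"""Curve construction, normal evolution and the backfat thickness marks."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure as skmeasure

from beefmetrics.backfat import (
    Curve,
    ThicknessProfile,
    build_initial_curve,
    build_target_curve,
    evolve_between_curves,
    measure_backfat,
    ribeye_axis,
)
from beefmetrics.errors import CurveEvolutionError
from beefmetrics.phantoms import Ellipse


def circle(center, r, n=400):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Curve(np.asarray(center) + r * np.column_stack([np.cos(t), np.sin(t)]))


def brute_force_hull(points: np.ndarray) -> np.ndarray:
    """Andrew monotone chain convex hull (test-local oracle)."""
    pts = sorted(map(tuple, points))
    if len(pts) <= 2:
        return np.array(pts)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1], dtype=float)


class TestInitialCurve:
    def test_square_mask_gives_four_corner_hull(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:41, 20:51] = True
        hull = build_initial_curve(mask)
        assert len(hull.points) == 4
        assert set(map(tuple, hull.points.astype(int))) == {
            (20, 10), (50, 10), (50, 40), (20, 40),
        }

    def test_l_shape_hull_contains_mask(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:20] = True
        mask[40:50, 10:50] = True
        hull = build_initial_curve(mask)
        filled = hull.mask((60, 60))
        grown = ndi.binary_dilation(filled)  # hull raster boundary is inclusive
        assert np.all(grown[mask])
        assert filled.sum() >= mask.sum()

    def test_random_blob_matches_brute_force_hull(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((80, 80), dtype=bool)
        pts = rng.integers(15, 65, size=(60, 2))
        mask[pts[:, 1], pts[:, 0]] = True
        hull = build_initial_curve(mask)
        ys, xs = np.nonzero(mask)
        expect = brute_force_hull(np.column_stack([xs, ys]))
        assert set(map(tuple, hull.points)) == set(map(tuple, expect))

    def test_too_few_pixels_raises(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = mask[5, 6] = True
        with pytest.raises(CurveEvolutionError):
            build_initial_curve(mask)


class TestTargetCurve:
    def test_disk_in_disk_target_is_outer_circle(self):
        yy, xx = np.mgrid[0:240, 0:240]
        steak = (xx - 120) ** 2 + (yy - 120) ** 2 <= 100**2
        inner = circle((120, 120), 60)
        target = build_target_curve(steak, inner)
        radii = np.linalg.norm(target.points - [120, 120], axis=1)
        assert np.all(np.abs(radii - 100) <= 1.0)

    def test_contact_produces_disjoint_curves(self):
        # hull touching the steak boundary along the right arc
        yy, xx = np.mgrid[0:240, 0:240]
        steak = (xx - 100) ** 2 + (yy - 120) ** 2 <= 80**2
        inner = circle((120, 120), 60)  # touches steak boundary near x=180
        target = build_target_curve(steak, inner)
        inner_px = set(map(tuple, np.round(inner.points).astype(int)))
        target_px = set(map(tuple, np.round(target.points).astype(int)))
        assert not inner_px & target_px

    def test_matches_mask_union_oracle(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:200, 0:200]
        steak = (xx - 100) ** 2 / 90**2 + (yy - 100) ** 2 / 60**2 <= 1
        pts = np.column_stack([rng.uniform(60, 140, 40), rng.uniform(70, 130, 40)])
        inner = build_initial_curve_from_points(pts)
        target = build_target_curve(steak, inner)
        union = steak | inner.mask((200, 200))
        contour = max(skmeasure.find_contours(union.astype(float), 0.5), key=len)
        oracle = contour[:, ::-1]  # (row, col) -> (x, y)
        d1, _ = cKDTree(oracle).query(target.points)
        d2, _ = cKDTree(target.points).query(oracle)
        assert max(d1.max(), d2.max()) <= 1.5 + 2.0  # contact dilation may add 2 px


def build_initial_curve_from_points(pts: np.ndarray) -> Curve:
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return Curve(pts[hull.vertices])


class TestNormalEvolution:
    def test_concentric_circles_analytic_distance(self):
        res = evolve_between_curves(
            circle((100, 100), 50), circle((100, 100), 80), step=1.0, shape=(200, 200)
        )
        assert np.all(res.path_length >= 29.0)
        assert np.all(res.path_length <= 31.0)

    def test_near_zero_thickness(self):
        res = evolve_between_curves(
            circle((100, 100), 50), circle((100, 100), 51), step=1.0, shape=(200, 200)
        )
        assert np.all(res.path_length <= 2.0)

    def test_ellipse_in_circle_matches_analytic_marching(self):
        t = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        c = np.array([100.0, 100.0])
        a, b, R = 60.0, 35.0, 80.0
        inner = Curve(c + np.column_stack([a * np.cos(t), b * np.sin(t)]))
        res = evolve_between_curves(inner, circle((100, 100), R), step=1.0, shape=(200, 200))
        # oracle: from each start point, solve |p + s*n - c| = R along the
        # exact outward ellipse normal (closed form, no rasterization)
        for p, length in zip(res.start, res.path_length):
            d = p - c
            tt = np.arctan2(d[1] / b, d[0] / a)
            n = np.array([b * np.cos(tt), a * np.sin(tt)])
            n /= np.linalg.norm(n)
            qb = 2 * np.dot(d, n)
            qc = np.dot(d, d) - R**2
            s = (-qb + np.sqrt(qb**2 - 4 * qc)) / 2
            assert abs(length - s) <= 2.0

    def test_self_convergence_under_step_refinement(self):
        t = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        c = np.array([100.0, 100.0])
        inner = Curve(c + np.column_stack([60 * np.cos(t), 35 * np.sin(t)]))
        outer = circle((100, 100), 80)
        res1 = evolve_between_curves(inner, outer, step=1.0, shape=(200, 200))
        res01 = evolve_between_curves(inner, outer, step=0.1, shape=(200, 200))
        _, idx = cKDTree(res01.start).query(res1.start)
        assert np.max(np.abs(res1.path_length - res01.path_length[idx])) <= 2.0

    def test_stuck_points_raise_with_indices(self):
        # target region too small to ever be left: unreachable outward
        inner = circle((100, 100), 50)
        outer = circle((100, 100), 80)
        with pytest.raises(CurveEvolutionError, match="fail"):
            evolve_between_curves(inner, outer, step=1.0, max_iterations=5, shape=(200, 200))


class TestRibeyeAxis:
    def test_rotated_ellipse_direction_and_length(self):
        mask = Ellipse(200, 150, 120, 70, np.deg2rad(30)).mask((320, 420))
        axis = ribeye_axis(mask)
        angle = np.rad2deg(np.arctan2(axis.direction[1], axis.direction[0]))
        assert abs(angle - 30.0) <= 2.0
        assert abs(2 * axis.half_length - 240.0) / 240.0 <= 0.02

    def test_circle_is_degenerate_with_warning(self):
        mask = Ellipse(60, 60, 40, 40).mask((120, 120))
        with pytest.warns(UserWarning, match="degenerate"):
            axis = ribeye_axis(mask)
        assert axis.direction == (1.0, 0.0)

    def test_centroid_inside_bounding_box(self):
        mask = Ellipse(80, 60, 50, 25, 0.4).mask((140, 160))
        axis = ribeye_axis(mask)
        ys, xs = np.nonzero(mask)
        assert xs.min() <= axis.centroid[0] <= xs.max()
        assert ys.min() <= axis.centroid[1] <= ys.max()


class TestMeasureBackfat:
    def test_constant_thickness_marks(self, steak_phantom):
        img, truth = steak_phantom
        profile = measure_backfat(img, truth.masks["ribeye"])
        assert 18.0 <= profile.thickness_half <= 22.0
        assert 18.0 <= profile.thickness_threequarter <= 22.0

    def test_ramp_profile_monotone_and_accurate(self, steak_phantom_ramp):
        img, truth = steak_phantom_ramp
        profile = measure_backfat(img, truth.masks["ribeye"])
        th = profile.samples[:, 1]
        assert np.all(np.diff(th) >= -2.0)  # non-decreasing within tolerance
        # compare each mark with the local truth thickness (nearest band point)
        for key, measured in (
            ("half_point", profile.thickness_half),
            ("threequarter_point", profile.thickness_threequarter),
        ):
            p = np.array(profile.mark_points[key])
            i = np.argmin(np.linalg.norm(truth.profile_points - p, axis=1))
            assert abs(measured - truth.profile_thickness[i]) <= 2.0
        assert profile.thickness_half < profile.thickness_threequarter

    def test_marks_lie_on_band(self, steak_phantom):
        img, truth = steak_phantom
        profile = measure_backfat(img, truth.masks["ribeye"])
        band = ndi.binary_dilation(truth.masks["backfat_band"], iterations=1)
        for key in ("half_band_point", "threequarter_band_point"):
            x, y = np.round(profile.mark_points[key]).astype(int)
            assert band[y, x]

    def test_profile_contract(self, steak_phantom):
        img, truth = steak_phantom
        profile = measure_backfat(img, truth.masks["ribeye"])
        assert isinstance(profile, ThicknessProfile)
        assert np.all(profile.samples[:, 1] >= 0)
        assert np.all(np.diff(profile.samples[:, 0]) > 0)
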