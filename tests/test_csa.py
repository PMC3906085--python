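"""Plane-mesh sectioning, shape-free area, inscribed diameter, profiles."""

import numpy as np
import pytest
import trimesh

from vessel_csa.centerline import Centerline
from vessel_csa.csa import (
    build_profile,
    equivalent_diameter,
    inscribed_diameter,
    polygon_area,
    slice_mesh,
)
from vessel_csa.phantom import (
    crescent_inscribed_diameter,
    crescent_polygon,
)


def _circle_loop(r=2.0, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.c_[r * np.cos(t), r * np.sin(t), np.zeros(n)]


def grid_inscribed_oracle(poly2d: np.ndarray, n: int = 1200) -> float:
    """Brute-force largest inscribed circle: dense grid of interior points,
    distance to the polygon boundary, times two."""
    import shapely
    from shapely import contains_xy
    from shapely.geometry import Polygon

    P = Polygon(poly2d)
    minx, miny, maxx, maxy = P.bounds
    xs = np.linspace(minx, maxx, n)
    ys = np.linspace(miny, maxy, n)
    X, Y = np.meshgrid(xs, ys)
    inside = contains_xy(P, X.ravel(), Y.ravel())
    pts = shapely.points(np.c_[X.ravel()[inside], Y.ravel()[inside]])
    return float(2.0 * shapely.distance(P.exterior, pts).max())


class TestSliceMesh:
    def test_unit_cube_mid_plane_has_unit_area(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        loop = slice_mesh(box, [0, 0, 0], [0, 0, 1])
        assert polygon_area(loop) == pytest.approx(1.0, rel=1e-6)

    def test_oblique_cylinder_section_matches_cos_correction(self):
        """Cutting a cylinder at 30 degrees gives an ellipse of area
        pi r^2 / cos(30)."""
        cyl = trimesh.creation.cylinder(radius=2.0, height=20.0, sections=512)
        th = np.deg2rad(30)
        loop = slice_mesh(cyl, [0, 0, 0], [np.sin(th), 0, np.cos(th)])
        assert polygon_area(loop) == pytest.approx(np.pi * 4 / np.cos(th), rel=0.01)

    def test_plane_missing_mesh_is_error(self):
        sph = trimesh.creation.icosphere(3, radius=1.0)
        with pytest.raises(ValueError, match="intersect"):
            slice_mesh(sph, [0, 0, 5.0], [0, 0, 1])

    def test_nearest_loop_selected_when_plane_cuts_twice(self):
        """A plane through a U-bend cuts two lumens; the one around the
        centerline point is returned."""
        a = trimesh.creation.cylinder(radius=1.0, height=10.0, sections=64)
        b = a.copy()
        b.apply_translation([5.0, 0, 0])
        pair = trimesh.util.concatenate([a, b])
        loop = slice_mesh(pair, [0, 0, 0], [0, 0, 1])
        center2d = loop.mean(axis=0)
        assert np.linalg.norm(center2d[:2]) < 1.0  # wrapped the cylinder at x=0
        loop_b = slice_mesh(pair, [5.0, 0, 0], [0, 0, 1])
        assert np.linalg.norm(loop_b.mean(axis=0)[:2] - [5.0, 0]) < 1.0


class TestPolygonArea:
    def test_unit_square(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_area(sq[::-1]) == pytest.approx(1.0)  # orientation-free

    def test_invariant_under_rigid_rotation(self, rng):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        R = trimesh.transformations.random_rotation_matrix(rand=rng.random(3))[:3, :3]
        assert polygon_area(sq @ R.T) == pytest.approx(1.0, rel=1e-9)

    def test_random_simple_polygon_matches_monte_carlo(self, rng):
        """Shoelace area vs 10^6-point Monte-Carlo rejection sampling."""
        from shapely import contains_xy
        from shapely.geometry import Polygon

        t = np.sort(rng.uniform(0, 2 * np.pi, 12))
        r = rng.uniform(1.0, 2.0, 12)
        poly = np.c_[r * np.cos(t), r * np.sin(t)]
        area = polygon_area(np.c_[poly, np.zeros(12)])
        P = Polygon(poly)
        lo = poly.min(axis=0)
        hi = poly.max(axis=0)
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        mc = contains_xy(P, pts[:, 0], pts[:, 1]).mean() * np.prod(hi - lo)
        assert area == pytest.approx(mc, rel=0.002)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            polygon_area(np.zeros((2, 3)))


class TestInscribedDiameter:
    def test_circle(self):
        assert inscribed_diameter(_circle_loop(2.0)) == pytest.approx(4.0, rel=1e-3)

    def test_ellipse_minor_axis(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        ell = np.c_[2.13 * np.cos(t), 1.99 * np.sin(t), np.zeros_like(t)]
        assert inscribed_diameter(ell) == pytest.approx(3.98, abs=0.01)

    def test_crescent_matches_grid_oracle(self):
        """Non-convex case: grid + Nelder-Mead agrees with the brute-force
        oracle and the closed form R + offset - r."""
        poly = crescent_polygon(2.2, 1.6, 1.2, n=512)
        ours = inscribed_diameter(np.c_[poly, np.zeros(len(poly))])
        oracle = grid_inscribed_oracle(poly)
        assert ours == pytest.approx(oracle, rel=0.01)
        assert ours == pytest.approx(crescent_inscribed_diameter(2.2, 1.6, 1.2), rel=0.01)

    def test_isoperimetric_bound(self):
        for poly2d in (
            crescent_polygon(2.2, 1.6, 1.2, n=256),
            crescent_polygon(3.0, 2.0, 1.8, n=256),
        ):
            loop = np.c_[poly2d, np.zeros(len(poly2d))]
            assert inscribed_diameter(loop) <= equivalent_diameter(polygon_area(loop)) * (
                1 + 1e-6
            )


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "area,expected", [(12.566, 4.0), (13.2, 4.10), (np.pi, 2.0)]
    )
    def test_values(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected, abs=5e-3)

    def test_requires_positive_area(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)


def _straight_centerline(length=20.0, n=81, x=0.0, y=0.0):
    z = np.linspace(-length / 2, length / 2, n)
    pts = np.c_[np.full(n, x), np.full(n, y), z]
    s = z - z[0]
    tan = np.tile([0.0, 0.0, 1.0], (n, 1))
    return Centerline(pts, s, tan)


class TestBuildProfile:
    def test_cylinder_sections_match_analytic_area(self):
        cyl = trimesh.creation.cylinder(radius=2.0, height=24.0, sections=256)
        prof = build_profile(cyl, _straight_centerline(20.0), step=0.5)
        assert len(prof) > 20
        np.testing.assert_allclose(prof.areas, np.pi * 4, rtol=0.01)
        np.testing.assert_allclose(prof.inscribed_diams, 4.0, rtol=0.01)

    def test_oblique_axis_overestimates_but_tangent_planes_do_not(self):
        """For a tube at 30 degrees to z, fixed-z slicing inflates areas by
        1/cos(30); planes normal to the centerline tangent do not."""
        cyl = trimesh.creation.cylinder(radius=2.0, height=24.0, sections=256)
        th = np.deg2rad(30)
        R = trimesh.transformations.rotation_matrix(th, [1, 0, 0])
        tilted = cyl.copy()
        tilted.apply_transform(R)
        axis = R[:3, :3] @ np.array([0.0, 0.0, 1.0])
        n = 41
        z = np.linspace(-8, 8, n)
        pts = np.outer(z, axis)
        s = z - z[0]
        cl = Centerline(pts, s, np.tile(axis, (n, 1)))
        prof = build_profile(tilted, cl, step=0.5)
        np.testing.assert_allclose(prof.areas, np.pi * 4, rtol=0.03)
        # fixed-axis slicing for contrast
        fixed = slice_mesh(tilted, [0, 0, 0], [0, 0, 1])
        assert polygon_area(fixed) == pytest.approx(np.pi * 4 / np.cos(th), rel=0.02)

    def test_profile_invariant_under_rigid_rotation(self):
        cyl = trimesh.creation.cylinder(radius=2.0, height=24.0, sections=256)
        cl = _straight_centerline(20.0)
        base = build_profile(cyl, cl, step=1.0)
        R = trimesh.transformations.rotation_matrix(np.deg2rad(30), [1, 1, 0])
        rot = cyl.copy()
        rot.apply_transform(R)
        pts = cl.points @ R[:3, :3].T
        tans = cl.tangents @ R[:3, :3].T
        rot_cl = Centerline(pts, cl.arc_lengths, tans)
        rot_prof = build_profile(rot, rot_cl, step=1.0)
        np.testing.assert_allclose(rot_prof.areas, base.areas, rtol=0.005)

    def test_no_planes_cross_inside_lumen_on_curved_vessel(self, helix_mask):
        """After deviation repair, no two neighboring cutting planes intersect
        within the lumen."""
        from vessel_csa.centerline import (
            bezier_refine,
            extract_main_path,
            smooth_points,
            thin_skeleton,
        )
        from vessel_csa.csa import _planes_cross_inside
        from vessel_csa.mesh import curvature_smooth, marching_cubes
        from vessel_csa.volume_io import LabelMask

        lumen = LabelMask(
            helix_mask.lumen.astype(np.uint8), helix_mask.spacing, helix_mask.origin
        )
        mesh = curvature_smooth(marching_cubes(lumen), 20)
        sk = thin_skeleton(lumen)
        pts = np.asarray(helix_mask.origin) + np.asarray(
            extract_main_path(sk), float
        ) * np.asarray(helix_mask.spacing)
        cl = bezier_refine(smooth_points(pts, 5))
        prof = build_profile(mesh, cl, step=0.25)
        secs = prof.valid_sections
        crossings = sum(
            _planes_cross_inside(
                a.center, a.normal, a.area, b.center, b.normal, b.area
            )
            for a, b in zip(secs, secs[1:])
        )
        assert crossings == 0

    def test_csv_round_trip_schema(self, tmp_path):
        cyl = trimesh.creation.cylinder(radius=2.0, height=24.0, sections=64)
        prof = build_profile(cyl, _straight_centerline(20.0), step=1.0)
        path = str(tmp_path / "profile.csv")
        prof.write_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "s_mm",
            "area_mm2",
            "inscribed_diam_mm",
            "equiv_diam_mm",
            "flag",
        ]
        assert len(df) == len(prof.sections)
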