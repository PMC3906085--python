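"""Thinning, path pruning, smoothing, and sub-voxel Bezier refinement."""

import numpy as np
import pytest

from vessel_csa.centerline import (
    Centerline,
    bezier_refine,
    extract_main_path,
    resample,
    smooth_points,
    thin_skeleton,
)
from vessel_csa.volume_io import LabelMask


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return LabelMask(np.asarray(data, dtype=np.uint8), spacing)


class TestThinning:
    def test_single_voxel_is_its_own_skeleton(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1
        sk = thin_skeleton(_mask(data))
        assert sk.voxels == [(2, 2, 2)]

    def test_solid_cylinder_skeleton_hugs_axis(self):
        shape = (16, 16, 30)
        idx = np.indices(shape)
        data = ((idx[0] - 7.5) ** 2 + (idx[1] - 7.5) ** 2 <= 25.0).astype(np.uint8)
        sk = thin_skeleton(_mask(data))
        vox = np.asarray(sk.voxels, dtype=float)
        radial = np.sqrt((vox[:, 0] - 7.5) ** 2 + (vox[:, 1] - 7.5) ** 2)
        # every skeleton voxel within about one voxel of the true axis
        assert radial.max() <= 1.0 + 1e-9

    def test_solid_torus_skeleton_is_single_cycle(self):
        shape = (40, 40, 12)
        idx = np.indices(shape).astype(float)
        R, r = 12.0, 3.5
        rad = np.sqrt((idx[0] - 19.5) ** 2 + (idx[1] - 19.5) ** 2)
        data = ((rad - R) ** 2 + (idx[2] - 5.5) ** 2 <= r * r).astype(np.uint8)
        sk = thin_skeleton(_mask(data))
        degrees = [sk.graph.degree(n) for n in sk.graph.nodes]
        assert all(d == 2 for d in degrees)  # one closed loop, no branches

    def test_multi_component_mask_rejected(self):
        data = np.zeros((8, 8, 8))
        data[1, 1, 1] = 1
        data[6, 6, 6] = 1
        with pytest.raises(ValueError, match="components"):
            thin_skeleton(_mask(data))


def _path_mask(points, shape=(20, 20, 20)):
    data = np.zeros(shape)
    for p in points:
        data[p] = 1
    return _mask(data)


class TestMainPath:
    def test_path_shaped_skeleton_returned_in_order(self):
        pts = [(2, 2, k) for k in range(2, 15)]
        sk = thin_skeleton(_path_mask(pts))
        path = extract_main_path(sk)
        assert path == pts or path == pts[::-1]

    def test_y_shape_with_endpoints_skips_short_arm(self):
        long_a = [(2, 2, k) for k in range(2, 12)]
        long_b = [(2, 2 + j, 12 + j) for j in range(0, 6)]
        short = [(2 + j, 2, 12 + j) for j in range(1, 3)]
        sk = thin_skeleton(_path_mask(long_a + long_b + short, shape=(24, 24, 24)))
        path = extract_main_path(sk, endpoints=(long_a[0], long_b[-1]))
        assert short[0] not in path and short[-1] not in path

    def test_y_shape_diameter_matches_brute_force(self):
        """Graph-diameter pruning agrees with exhaustive all-pairs search."""
        import itertools

        import networkx as nx

        long_a = [(2, 2, k) for k in range(2, 12)]
        long_b = [(2, 2 + j, 12 + j) for j in range(0, 6)]
        short = [(2 + j, 2, 12 + j) for j in range(1, 4)]
        sk = thin_skeleton(_path_mask(long_a + long_b + short, shape=(24, 24, 24)))
        path = extract_main_path(sk)
        length = sum(
            np.linalg.norm(np.subtract(a, b)) for a, b in zip(path, path[1:])
        )
        best = 0.0
        for u, v in itertools.combinations(sk.graph.nodes, 2):
            d = nx.shortest_path_length(sk.graph, u, v, weight="weight")
            best = max(best, d)
        assert length == pytest.approx(best, abs=1e-9)

    def test_endpoint_snapping_within_3_voxels(self):
        pts = [(2, 2, k) for k in range(2, 15)]
        sk = thin_skeleton(_path_mask(pts))
        path = extract_main_path(sk, endpoints=((3, 3, 2), (2, 2, 14)))
        assert path[0] == (2, 2, 2)
        with pytest.raises(ValueError, match="voxels"):
            extract_main_path(sk, endpoints=((15, 15, 2), (2, 2, 14)))


class TestSmoothPoints:
    def test_collinear_points_unchanged(self):
        pts = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        out = smooth_points(pts, 5)
        np.testing.assert_allclose(out, pts, atol=1e-12)

    def test_zigzag_amplitude_crushed(self):
        n = 41
        pts = np.column_stack(
            [np.arange(n, dtype=float), np.where(np.arange(n) % 2 == 0, 0.5, -0.5), np.zeros(n)]
        )
        out = smooth_points(pts, 5)
        assert np.abs(out[5:-5, 1]).max() < 0.3

    def test_endpoints_exactly_preserved(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 3)).cumsum(axis=0)
        for window in (3, 5, 15):
            out = smooth_points(pts, window if window % 2 else window + 1)
            np.testing.assert_array_equal(out[0], pts[0])
            np.testing.assert_array_equal(out[-1], pts[-1])

    def test_window_validation(self):
        pts = np.zeros((10, 3))
        with pytest.raises(ValueError):
            smooth_points(pts, 4)
        with pytest.raises(ValueError):
            smooth_points(pts, 11)


def _jagged_helix(n=120, radius=10.0, pitch=20.0, spacing=0.4):
    """Voxel-grid discretization of a helix: the jagged input to refinement."""
    turns = 1.0
    theta = np.linspace(0, 2 * np.pi * turns, n)
    true = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), pitch * theta / (2 * np.pi)]
    )
    jag = np.round(true / spacing) * spacing
    # deduplicate consecutive identical grid points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(jag, axis=0), axis=1) > 1e-12])
    return true, jag[keep]


def _dist_to_helix(points, radius=10.0, pitch=20.0):
    theta_dense = np.linspace(-0.5, 2 * np.pi + 0.5, 20000)
    dense = np.column_stack(
        [
            radius * np.cos(theta_dense),
            radius * np.sin(theta_dense),
            pitch * theta_dense / (2 * np.pi),
        ]
    )
    from scipy.spatial import cKDTree

    d, _ = cKDTree(dense).query(points)
    return d


class TestBezierRefine:
    def test_collinear_controls_stay_collinear(self):
        pts = np.column_stack([np.linspace(0, 10, 12), np.zeros(12), np.zeros(12)])
        cl = bezier_refine(pts)
        np.testing.assert_allclose(cl.points[:, 1:], 0.0, atol=1e-9)

    def test_helix_jaggedness_removed_to_subvoxel(self):
        """RMS distance of the refined curve to the true helix is below half a
        voxel and strictly below the jagged input's RMS."""
        spacing = 0.4
        _, jag = _jagged_helix(spacing=spacing)
        cl = bezier_refine(smooth_points(jag, 5))
        rms_raw = np.sqrt((_dist_to_helix(jag) ** 2).mean())
        rms_ref = np.sqrt((_dist_to_helix(cl.points) ** 2).mean())
        assert rms_ref < 0.5 * spacing
        assert rms_ref < rms_raw

    def test_total_curvature_reduced(self):
        def total_sq_turn(p):
            d = np.diff(p, axis=0)
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
            return float((np.diff(d, axis=0) ** 2).sum())

        _, jag = _jagged_helix()
        cl = bezier_refine(smooth_points(jag, 5))
        dense_jag = resample(
            Centerline(
                jag,
                np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(jag, axis=0), axis=1))]),
                np.tile([0.0, 0.0, 1.0], (len(jag), 1)),
            ),
            step=0.25,
        )
        assert total_sq_turn(cl.points) < total_sq_turn(dense_jag.points)

    def test_length_not_inflated(self):
        _, jag = _jagged_helix()
        sm = smooth_points(jag, 5)
        seg = np.linalg.norm(np.diff(sm, axis=0), axis=1).sum()
        cl = bezier_refine(sm)
        assert cl.length <= seg * 1.01

    def test_duplicate_points_deduplicated_with_warning(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.warns(UserWarning, match="repeated"):
            cl = bezier_refine(pts)
        assert cl.length > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            bezier_refine(np.zeros((3, 3)) + np.arange(3)[:, None])

    def test_tangents_unit_norm_and_endpoints_clamped(self):
        _, jag = _jagged_helix()
        cl = bezier_refine(smooth_points(jag, 5))
        np.testing.assert_allclose(np.linalg.norm(cl.tangents, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(cl.points[0], jag[0], atol=1e-12)
        np.testing.assert_allclose(cl.points[-1], jag[-1], atol=1e-12)


class TestResample:
    def _line(self):
        pts = np.column_stack([np.linspace(0, 10, 41), np.zeros(41), np.zeros(41)])
        s = np.linspace(0, 10, 41)
        t = np.tile([1.0, 0, 0], (41, 1))
        return Centerline(pts, s, t)

    def test_line_10mm_step_1_gives_11_points(self):
        out = resample(self._line(), 1.0)
        assert len(out) == 11
        np.testing.assert_allclose(out.points[-1], [10, 0, 0], atol=1e-9)

    def test_idempotent(self):
        once = resample(self._line(), 0.7)
        twice = resample(once, 0.7)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-9)

    def test_length_preserved(self):
        out = resample(self._line(), 0.3)
        assert out.length == pytest.approx(10.0, rel=1e-3)

    def test_step_must_be_positive(self):
        with pytest.raises(ValueError):
            resample(self._line(), 0.0)


class TestPipelineCenterlineAccuracy:
    def test_refined_centerline_subvoxel_on_noisy_tube(self, tube_mask):
        """On the default blurred+noisy tube the refined centerline tracks the
        true axis to well under half a voxel RMS."""
        sk = thin_skeleton(
            LabelMask(tube_mask.lumen.astype(np.uint8), tube_mask.spacing, tube_mask.origin)
        )
        path = extract_main_path(sk)
        pts = np.asarray(tube_mask.origin) + np.asarray(path, float) * np.asarray(
            tube_mask.spacing
        )
        cl = bezier_refine(smooth_points(pts, 5))
        radial = np.sqrt((cl.points[:, 0] - 9.6) ** 2 + (cl.points[:, 1] - 9.6) ** 2)
        assert np.sqrt((radial**2).mean()) <= 0.5 * 0.4
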