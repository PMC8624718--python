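import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ssetopo.geometry import (
    DegenerateCloudError,
    SkeletonGraph,
    pca_axis,
    segment_distance,
    skeleton_distance,
)
from ssetopo.model import SSEType, Skeleton, Trace


def _trace(a, b, tid="T"):
    return Trace(tid, SSEType.HELIX, np.asarray(a, float), np.asarray(b, float))


def _ideal_helix(n_res=20, radius=2.3, rise=1.5, twist_deg=100.0):
    """Backbone points of an ideal α-helix around the z-axis."""
    t = np.arange(n_res)
    ang = np.deg2rad(twist_deg) * t
    return np.c_[radius * np.cos(ang), radius * np.sin(ang), rise * t]


class TestPCAAxis:
    def test_collinear_points_recovered_exactly(self):
        pts = np.array([[k, 0.0, 0.0] for k in range(11)])
        tr = pca_axis(pts)
        np.testing.assert_allclose(tr.p_start, [0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(tr.p_end, [10, 0, 0], atol=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 3)) * np.array([6.0, 1.0, 0.5])
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        base = pca_axis(pts)
        rotated = pca_axis(pts @ R.T)
        ends = np.array([base.p_start @ R.T, base.p_end @ R.T])
        got = np.array([rotated.p_start, rotated.p_end])
        # orientation convention may flip the endpoint order under rotation
        assert (
            np.allclose(got, ends, atol=1e-8)
            or np.allclose(got, ends[::-1], atol=1e-8)
        )

    def test_helix_axis_within_half_angstrom(self):
        # frozen oracle: the generating axis of the ideal helix is the z-axis
        pts = _ideal_helix()
        tr = pca_axis(pts)
        samples = np.linspace(tr.p_start, tr.p_end, 50)
        # distance of fitted-line samples to the true axis (x=y=0)
        d = np.sqrt(samples[:, 0] ** 2 + samples[:, 1] ** 2)
        assert np.sqrt(np.mean(d**2)) < 0.5

    def test_axis_length_equals_projection_extent(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(30, 3)) * np.array([8.0, 2.0, 1.0])
        tr = pca_axis(pts)
        axis = (tr.p_end - tr.p_start) / np.linalg.norm(tr.p_end - tr.p_start)
        proj = (pts - pts.mean(axis=0)) @ axis
        assert tr.length == pytest.approx(proj.max() - proj.min(), abs=1e-8)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(DegenerateCloudError):
            pca_axis(np.ones((5, 3)))

    def test_eigenvalue_tie_warns_and_is_deterministic(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        with pytest.warns(UserWarning, match="ambiguous"):
            first = pca_axis(pts)
        with pytest.warns(UserWarning):
            second = pca_axis(pts)
        np.testing.assert_allclose(first.p_start, second.p_start)
        np.testing.assert_allclose(first.p_end, second.p_end)


class TestSegmentDistance:
    def test_parallel_fully_overlapping_offset(self):
        a = _trace([0, 0, 0], [10, 0, 0])
        b = _trace([0, 5, 0], [10, 5, 0])
        assert segment_distance(a, b) == pytest.approx(5.0)

    def test_crossing_segments_touch(self):
        a = _trace([-1, 0, 0], [1, 0, 0])
        b = _trace([0, -1, 0], [0, 1, 0])
        assert segment_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(42)
        ts = np.linspace(0.0, 1.0, 1000)
        for _ in range(30):
            p = rng.uniform(0, 50, (2, 3))
            q = rng.uniform(0, 50, (2, 3))
            a, b = _trace(*p, "A"), _trace(*q, "B")
            pa = p[0] + ts[:, None] * (p[1] - p[0])
            qa = q[0] + ts[:, None] * (q[1] - q[0])
            from scipy.spatial.distance import cdist

            oracle = cdist(pa, qa).min()
            assert abs(segment_distance(a, b) - oracle) <= 0.05

    def test_symmetry_and_endpoint_bound_and_rigid_invariance(self):
        rng = np.random.default_rng(7)
        R = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        shift = np.array([3.0, -8.0, 2.0])
        for _ in range(50):
            p = rng.uniform(0, 30, (2, 3))
            q = rng.uniform(0, 30, (2, 3))
            a, b = _trace(*p, "A"), _trace(*q, "B")
            d = segment_distance(a, b)
            assert d == pytest.approx(segment_distance(b, a))
            endpoint_min = min(
                np.linalg.norm(pi - qi) for pi in p for qi in q
            )
            assert d <= endpoint_min + 1e-9
            a2 = _trace(p[0] @ R.T + shift, p[1] @ R.T + shift, "A")
            b2 = _trace(q[0] @ R.T + shift, q[1] @ R.T + shift, "B")
            assert segment_distance(a2, b2) == pytest.approx(d, abs=1e-8)


class TestSkeletonDistance:
    def _chain(self, points):
        return Skeleton(np.asarray(points, float), link_radius=1.5)

    def test_straight_chain(self):
        sk = self._chain([[k, 0, 0] for k in range(11)])
        d = skeleton_distance(sk, np.array([0.0, 0, 0]), np.array([10.0, 0, 0]))
        assert d == pytest.approx(10.0, abs=0.01)

    def test_l_shaped_chain_follows_the_corner(self):
        leg1 = [[k, 0, 0] for k in range(11)]
        leg2 = [[10, k, 0] for k in range(1, 11)]
        # link radius below the corner diagonal (sqrt 2) so the path cannot
        # cut the corner
        sk = Skeleton(np.asarray(leg1 + leg2, float), link_radius=1.2)
        d = skeleton_distance(sk, np.array([0.0, 0, 0]), np.array([10.0, 10.0, 0]))
        assert d == pytest.approx(20.0, abs=0.2)  # vs Euclidean 14.14

    def test_disconnected_components_fall_back_to_euclidean(self):
        sk = self._chain([[0, 0, 0], [1, 0, 0], [30, 0, 0], [31, 0, 0]])
        p, q = np.array([0.0, 0, 0]), np.array([31.0, 0, 0])
        assert skeleton_distance(sk, p, q) == pytest.approx(31.0)

    def test_never_shorter_than_straight_line_minus_snap_slack(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 20, (80, 3))
        sk = Skeleton(pts, link_radius=4.0)
        g = SkeletonGraph(sk)
        for _ in range(20):
            p, q = rng.uniform(0, 20, 3), rng.uniform(0, 20, 3)
            assert g.distance(p, q) >= np.linalg.norm(p - q) - 2 * sk.link_radius - 1e-9

    def test_monotone_in_link_radius_while_connected(self):
        pts = np.array([[k * 0.9, math.sin(k) * 0.5, 0.0] for k in range(25)])
        p, q = pts[0], pts[-1]
        dists = [
            SkeletonGraph(Skeleton(pts, link_radius=r)).distance(p, q)
            for r in (1.2, 2.0, 4.0, 8.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_distance_matrix_matches_single_queries(self):
        pts = np.array([[k, 0, 0] for k in range(15)], float)
        g = SkeletonGraph(Skeleton(pts, link_radius=1.5))
        queries = np.array([[0.2, 0.1, 0], [7.0, -0.3, 0], [14.0, 0.2, 0]])
        mat = g.distance_matrix(queries)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert mat[i, j] == pytest.approx(
                        g.distance(queries[i], queries[j]), abs=1e-8
                    )
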