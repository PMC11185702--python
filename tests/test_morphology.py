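import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import RBFInterpolator

from neckcompare import (
    apply_transform,
    fit_landmark_transform,
    longest_neurite_from_point,
    mirror,
    resample,
    to_dotprops,
)
from neckcompare.errors import ConditioningError

from conftest import make_skeleton, random_tree


class TestResample:
    def test_straight_chain_10um_at_1um_spacing(self):
        """A single 10 um edge becomes 11 nodes with equal 1 um gaps."""
        sk = make_skeleton([[0, 0, 0], [10_000, 0, 0]], [-1, 0])
        rs = resample(sk, 1000.0)
        assert rs.n_nodes == 11
        np.testing.assert_allclose(rs.edge_lengths(), 1000.0)

    def test_spacing_larger_than_cable_keeps_original_nodes(self):
        sk = make_skeleton([[0, 0, 0], [5000, 0, 0], [5000, 4000, 0]], [-1, 0, 1])
        rs = resample(sk, 1e6)
        assert rs.n_nodes == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_cable_length_preserved_and_edges_bounded(self, seed):
        rng = np.random.default_rng(seed)
        sk = random_tree(rng, n_nodes=40)
        spacing = 1500.0
        rs = resample(sk, spacing)
        assert rs.cable_length() == pytest.approx(sk.cable_length(), rel=1e-6)
        assert np.all(rs.edge_lengths() <= spacing + 1e-6)
        # branch and end points preserved exactly
        orig = {tuple(np.round(c, 6)) for c in sk.coords()}
        new = {tuple(np.round(c, 6)) for c in rs.coords()}
        assert orig <= new

    def test_nonpositive_spacing_rejected(self):
        sk = make_skeleton([[0, 0, 0], [1, 0, 0]], [-1, 0])
        with pytest.raises(ValueError):
            resample(sk, 0)


class TestDotprops:
    def test_collinear_points_have_unit_alpha_and_x_tangent(self):
        pts = np.array([[i * 1000.0, 0, 0] for i in range(10)])
        sk = make_skeleton(pts, [-1] + list(range(9)))
        dp = to_dotprops(sk, k=5, spacing=1000.0)
        np.testing.assert_allclose(dp.tangents, [[1, 0, 0]] * len(dp), atol=1e-12)
        np.testing.assert_allclose(dp.alpha, 1.0, atol=1e-12)

    def test_corner_tangent_between_arm_directions(self):
        """At a right-angle corner the k-neighbourhood principal direction
        is strictly between the +x and +y arm directions (computed by hand
        as the leading eigenvector of the neighbourhood covariance)."""
        pts = np.array(
            [[2000, 0, 0], [1000, 0, 0], [0, 0, 0], [0, 1000, 0], [0, 2000, 0]],
            dtype=float,
        )
        sk = make_skeleton(pts, [-1, 0, 1, 2, 3])
        dp = to_dotprops(sk, k=5, spacing=10_000.0)
        corner = np.argmin(np.linalg.norm(dp.points, axis=1))
        t = dp.tangents[corner]
        # hand oracle: eigh of the covariance of all five points
        c = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(c.T @ c)
        expect = evecs[:, -1]
        expect = expect if tuple(expect) >= tuple(-expect) else -expect
        np.testing.assert_allclose(t, expect, atol=1e-9)
        assert abs(t[0]) > 0 and abs(t[1]) > 0  # strictly between the arms
        assert dp.alpha[corner] < 1

    def test_single_node_fallback(self):
        sk = make_skeleton([[5, 5, 5]], [-1])
        dp = to_dotprops(sk, k=5, spacing=1000.0)
        assert len(dp) == 1
        np.testing.assert_allclose(dp.tangents, [[1, 0, 0]])
        assert dp.alpha[0] == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_tangents_unit_norm(self, seed):
        rng = np.random.default_rng(seed)
        dp = to_dotprops(random_tree(rng, 30), k=5, spacing=2000.0)
        np.testing.assert_allclose(np.linalg.norm(dp.tangents, axis=1), 1.0, atol=1e-9)
        assert np.all((dp.alpha >= 0) & (dp.alpha <= 1))


def _all_path_lengths(sk, entry):
    """Oracle: exhaustively enumerate entry-to-leaf path lengths."""
    pts = sk.coords()
    ids = list(sk.nodes["node_id"].astype(int))
    idx = {n: i for i, n in enumerate(ids)}
    adj = {n: [] for n in ids}
    for r in sk.nodes.itertuples():
        if int(r.parent_id) != -1:
            a, b = int(r.node_id), int(r.parent_id)
            w = float(np.linalg.norm(pts[idx[a]] - pts[idx[b]]))
            adj[a].append((b, w))
            adj[b].append((a, w))
    start = ids[int(np.argmin(np.linalg.norm(pts - entry, axis=1)))]
    out = {}
    stack = [(start, None, 0.0)]
    while stack:
        node, prev, dist = stack.pop()
        nxt = [(v, w) for v, w in adj[node] if v != prev]
        if not nxt and node != start:
            out[node] = dist
        for v, w in nxt:
            stack.append((v, node, dist + w))
    return out


class TestLongestNeurite:
    def test_unbranched_chain_is_identity(self):
        sk = make_skeleton([[0, 0, 0], [1000, 0, 0], [2000, 0, 0]], [-1, 0, 1])
        ln = longest_neurite_from_point(sk, [0, 0, 0])
        assert ln.n_nodes == 3
        assert ln.cable_length() == pytest.approx(sk.cable_length())

    def test_y_tree_takes_longer_arm(self):
        """30 um vs 50 um arms from the stem: the 50 um arm wins (oracle:
        enumerate both root-to-leaf paths)."""
        coords = [[0, 0, 0], [0, 10_000, 0], [30_000, 10_000, 0], [-50_000, 10_000, 0]]
        sk = make_skeleton(coords, [-1, 0, 1, 1])
        ln = longest_neurite_from_point(sk, [0, 0, 0])
        assert ln.cable_length() == pytest.approx(60_000.0)
        assert 4 in set(ln.nodes["node_id"])

    def test_equal_arms_tie_breaks_to_smaller_leaf_id(self):
        coords = [[0, 0, 0], [0, 1000, 0], [1000, 1000, 0], [-1000, 1000, 0]]
        sk = make_skeleton(coords, [-1, 0, 1, 1])
        ln = longest_neurite_from_point(sk, [0, 0, 0])
        assert int(ln.nodes["node_id"].iloc[-1]) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sk = random_tree(rng, n_nodes=25)
        entry = rng.uniform(0, 30_000, 3)
        ln = longest_neurite_from_point(sk, entry)
        oracle = _all_path_lengths(sk, entry)
        assert ln.cable_length() == pytest.approx(max(oracle.values()), rel=1e-9)


class TestMirror:
    def test_point_example(self):
        np.testing.assert_allclose(
            mirror(np.array([[10.0, 5.0, 5.0]]), "x", 0.0), [[-10, 5, 5]]
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_involution_and_distance_preservation(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-100, 100, (12, 3))
        pos = float(rng.uniform(-10, 10))
        m = mirror(pts, "y", pos)
        np.testing.assert_allclose(mirror(m, "y", pos), pts, atol=1e-9)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d1 = np.linalg.norm(m[:, None] - m[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestThinPlateSpline:
    def test_identity_fit(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (10, 3))
        t = fit_landmark_transform(src, src)
        np.testing.assert_allclose(t.affine_part[:, :3], np.eye(3), atol=1e-8)
        np.testing.assert_allclose(t.kernel_weights, 0, atol=1e-8)

    def test_affine_pair_recovered_on_held_out_points(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 100, (20, 3))
        A = np.array([[1.1, 0.2, 0], [-0.1, 0.9, 0.05], [0, 0.1, 1.05]])
        b = np.array([3.0, -2.0, 1.0])
        dst = src @ A.T + b
        t = fit_landmark_transform(src, dst)
        probes = rng.uniform(0, 100, (100, 3))
        np.testing.assert_allclose(
            apply_transform(t, probes), probes @ A.T + b, atol=1e-6
        )

    def test_landmarks_interpolated_exactly(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 100, (30, 3))
        dst = src + rng.normal(0, 5, src.shape)
        t = fit_landmark_transform(src, dst)
        np.testing.assert_allclose(apply_transform(t, src), dst, atol=1e-6)

    def test_2110_landmark_pairs_fit(self):
        """A full-size landmark table (synthetic coordinates) fits cleanly."""
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 300_000, (2110, 3))
        dst = 1.05 * src + 2000.0 + 500.0 * np.sin(src / 40_000.0)
        t = fit_landmark_transform(src, dst)
        err = np.abs(apply_transform(t, src) - dst)
        assert err.max() < 1e-3  # nm scale: interpolation to numerical noise

    def test_matches_independent_kernel_evaluation(self):
        """Probe-point values equal a hand-coded evaluation of the TPS sum
        and scipy's RBF interpolator with the same biharmonic kernel."""
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 50, (15, 3))
        dst = src + rng.normal(0, 3, src.shape)
        t = fit_landmark_transform(src, dst)
        probes = rng.uniform(0, 50, (10, 3))
        # hand evaluation of affine + kernel sum
        expect = np.empty((10, 3))
        for i, p in enumerate(probes):
            r = np.linalg.norm(p - src, axis=1)
            expect[i] = t.affine_part @ np.append(p, 1.0) + r @ t.kernel_weights
        np.testing.assert_allclose(apply_transform(t, probes), expect, atol=1e-9)
        # independent cross-check: scipy RBF with phi(r) = -r, smoothing 0
        rbf = RBFInterpolator(src, dst, kernel="linear", degree=1)
        np.testing.assert_allclose(apply_transform(t, probes), rbf(probes), atol=1e-6)

    def test_coplanar_landmarks_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], float)
        with pytest.raises(ConditioningError):
            fit_landmark_transform(src, src + 1)

    def test_too_few_landmarks_rejected(self):
        src = np.eye(3)
        with pytest.raises(ConditioningError):
            fit_landmark_transform(src, src)
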