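"""Transect slicing, adaptive clustering, and trunk candidate validation."""

import numpy as np
import pytest

import stemscan as ss
from stemscan.detect import candidates_to_dataframe


def brute_force_clusters(xy, r, params):
    """O(n^2) union-find oracle for the adaptive-threshold clustering."""
    n = len(xy)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            rm = 0.5 * (r[i] + r[j])
            thr = params.k * max(
                ss.adjacent_distance(rm, rm, params.delta_phi),
                ss.adjacent_distance(rm, rm, params.delta_theta),
            )
            if np.linalg.norm(xy[i] - xy[j]) < thr:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values() if len(g) >= params.min_cluster_size}


def make_slice(xy, ranges, z=0.0):
    """Wrap planar points (with ranges) as a breast-height slice."""
    xy = np.asarray(xy, float)
    cloud = ss.PointCloud(
        xyz=np.column_stack([xy, np.full(len(xy), z)]),
        range_r=np.asarray(ranges, float),
        theta=np.zeros(len(xy)),
        phi=np.zeros(len(xy)),
    )
    return ss.slice_transect(cloud, center_z=z, half_thickness=0.05)


def arc_points(cx, cy, r, n, span=np.pi, start=None, jitter=0.0, rng=None):
    if start is None:
        start = np.arctan2(-cy, -cx) - span / 2  # face the origin
    t = start + np.linspace(0, span, n)
    pts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
    if jitter and rng is not None:
        pts = pts + rng.normal(0, jitter, pts.shape)
    return pts


class TestSliceTransect:
    def test_boundary_arithmetic(self):
        cloud = ss.PointCloud(xyz=[[0, 0, 1.26], [0, 0, 1.30], [0, 0, 1.40]])
        sl = ss.slice_transect(cloud, center_z=1.3, half_thickness=0.05)
        np.testing.assert_allclose(sl.cloud.z, [1.26, 1.30])

    def test_empty_slice_is_not_an_error(self):
        cloud = ss.PointCloud(xyz=np.zeros((5, 3)))
        assert len(ss.slice_transect(cloud, 1.3, 0.05)) == 0

    def test_matches_linear_scan(self, rng):
        xyz = rng.uniform(-2, 2, size=(500, 3))
        cloud = ss.PointCloud(xyz=xyz)
        sl = ss.slice_transect(cloud, center_z=0.3, half_thickness=0.1)
        expected = np.count_nonzero(np.abs(xyz[:, 2] - 0.3) <= 0.1)
        assert len(sl) == expected


class TestClusterThreshold:
    @pytest.mark.parametrize(
        "dab,dac,k,expected", [(0.02, 0.03, 1.5, 0.045), (0.0, 0.0, 1.5, 0.0)]
    )
    def test_examples(self, dab, dac, k, expected):
        assert ss.cluster_threshold(dab, dac, k) == pytest.approx(expected)

    def test_matches_max_then_scale(self, rng):
        d1 = rng.uniform(0, 0.1, 100)
        d2 = rng.uniform(0, 0.1, 100)
        np.testing.assert_allclose(
            ss.cluster_threshold(d1, d2, 1.5), 1.5 * np.maximum(d1, d2)
        )


class TestClusterTransect:
    def params(self, **kw):
        kw.setdefault("delta_theta", 0.1667)
        kw.setdefault("delta_phi", 0.1)
        kw.setdefault("min_cluster_size", 5)
        return ss.ClusterParams(**kw)

    def test_two_distant_stems_two_clusters(self, rng):
        a = arc_points(5.0, 0.0, 0.06, 40, jitter=1e-4, rng=rng)
        b = arc_points(5.0, 1.5, 0.06, 40, jitter=1e-4, rng=rng)
        xy = np.vstack([a, b])
        sl = make_slice(xy, np.linalg.norm(xy, axis=1))
        clusters = ss.cluster_transect(sl, self.params())
        assert len(clusters) == 2

    def test_single_dense_arc_one_cluster(self, rng):
        a = arc_points(4.0, 2.0, 0.08, 60, jitter=1e-4, rng=rng)
        sl = make_slice(a, np.linalg.norm(a, axis=1))
        assert len(ss.cluster_transect(sl, self.params())) == 1

    def test_matches_brute_force_union_find(self, rng):
        """Oracle equivalence on random small slices."""
        params = self.params(min_cluster_size=1)
        for trial in range(5):
            n = int(rng.integers(20, 200))
            centers = rng.uniform(-5, 5, size=(int(rng.integers(1, 5)), 2))
            pts = np.vstack(
                [c + rng.normal(0, 0.02, size=(n // len(centers) + 1, 2)) for c in centers]
            )[:n]
            r = np.linalg.norm(pts, axis=1)
            sl = make_slice(pts, r)
            fast = {frozenset(c.tolist()) for c in ss.cluster_transect(sl, params)}
            slow = brute_force_clusters(pts, r, params)
            assert fast == slow

    def test_partition_and_permutation_invariance(self, rng):
        pts = rng.normal(0, 1.0, size=(120, 2)) + [4, 0]
        r = np.linalg.norm(pts, axis=1)
        params = self.params(min_cluster_size=1)
        sl = make_slice(pts, r)
        clusters = ss.cluster_transect(sl, params)
        allidx = np.sort(np.concatenate(clusters))
        np.testing.assert_array_equal(allidx, np.arange(len(pts)))  # partition
        perm = rng.permutation(len(pts))
        sl2 = make_slice(pts[perm], r[perm])
        clusters2 = ss.cluster_transect(sl2, params)
        orig = {frozenset(c.tolist()) for c in clusters}
        permd = {frozenset(perm[c].tolist()) for c in clusters2}
        assert orig == permd

    def test_missing_backrefs_error(self):
        cloud = ss.PointCloud(xyz=np.zeros((10, 3)))
        sl = ss.slice_transect(cloud, 0.0, 0.1)
        sl.cloud.range_r = None
        with pytest.raises(ValueError):
            ss.cluster_transect(sl, self.params())


class TestDetectTrunks:
    def test_simulated_plot_all_stems_found(self, coarse_config):
        """Fully visible stems on a small simulated plot are each accepted."""
        plot = ss.generate_plot(
            extent=8.0, vacancy_prob=0.0, position_jitter_sd=0.0,
            crown_elements_per_tree=0, seed=4,
        )
        records, truth = ss.simulate_scan(
            plot, scanner_pos=(0.0, 0.0, 1.5), config=coarse_config, seed=1
        )
        cloud = ss.build_cloud(records, coarse_config)
        params = ss.ClusterParams.from_scanner(coarse_config)
        cands = ss.detect_trunks(cloud, params, slice_center_z=-0.2)
        accepted = [c for c in cands if c.status == "accepted"]
        est = np.array([[c.circle.xc, c.circle.yc] for c in accepted])
        m = ss.match_trees(est, truth[["x_m", "y_m"]].to_numpy(), 0.5)
        assert m.correct == len(truth)
        assert m.false == 0

    def test_short_arc_rejected_by_diameter_gate(self, rng):
        """A <20 degree arc with range noise fits an implausible diameter
        (its sagitta is at the noise level) and is rejected, not reported."""
        pts = arc_points(3.0, 0.0, 0.08, 30, span=np.deg2rad(15), jitter=3e-3, rng=rng)
        cloud = ss.PointCloud(
            xyz=np.column_stack([pts, np.full(30, 1.3)]),
            range_r=np.linalg.norm(pts, axis=1),
            theta=np.zeros(30),
            phi=np.zeros(30),
        )
        params = ss.ClusterParams(min_cluster_size=5)
        cands = ss.detect_trunks(cloud, params)
        assert len(cands) == 1
        assert cands[0].status == "rejected_diameter"
        d = cands[0].circle.diameter
        assert d > params.dbh_max or d < params.dbh_min

    def test_collinear_cluster_rejected_degenerate(self):
        n = 20
        pts = np.column_stack([np.linspace(4, 4.001, n), np.linspace(0, 0.01, n)])
        cloud = ss.PointCloud(
            xyz=np.column_stack([pts, np.full(n, 1.3)]),
            range_r=np.linalg.norm(pts, axis=1),
            theta=np.zeros(n),
            phi=np.zeros(n),
        )
        cands = ss.detect_trunks(cloud, ss.ClusterParams(min_cluster_size=5))
        assert len(cands) == 1
        assert cands[0].status == "rejected_degenerate"

    def test_report_dataframe(self, rng):
        pts = arc_points(4.0, 0.0, 0.07, 50, jitter=1e-4, rng=rng)
        cloud = ss.PointCloud(
            xyz=np.column_stack([pts, np.full(50, 1.3)]),
            range_r=np.linalg.norm(pts, axis=1),
            theta=np.zeros(50),
            phi=np.zeros(50),
        )
        cands = ss.detect_trunks(cloud, ss.ClusterParams())
        df = candidates_to_dataframe(cands)
        assert list(df.status) == ["accepted"]
        assert df.diameter_m.iloc[0] == pytest.approx(0.14, abs=5e-3)
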