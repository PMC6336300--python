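"""DBH re-slice, KNN top filter, height estimation, and the full pipeline."""

import numpy as np
import pytest

import stemscan as ss
from stemscan.errors import DegenerateFitError
from stemscan.metrics import tree_records_to_dataframe


def brute_knn_means(pts, k):
    """Exhaustive O(M^2) oracle for per-point mean KNN distance."""
    m = len(pts)
    out = np.empty(m)
    for i in range(m):
        d = np.sort(np.linalg.norm(pts - pts[i], axis=1))
        out[i] = d[1 : k + 1].mean()
    return out


class TestExtractTop:
    def test_window(self):
        state = ss.extract_top(np.array([[0, 0, 8.0], [0, 0, 7.8], [0, 0, 7.4]]))
        assert state.m == 2
        assert state.z_max == 8.0

    def test_single_point(self):
        state = ss.extract_top(np.array([[1, 2, 3.0]]))
        assert state.m == 1

    def test_matches_linear_scan(self, rng):
        pts = rng.uniform(0, 10, size=(300, 3))
        state = ss.extract_top(pts)
        z_max = pts[:, 2].max()
        assert state.m == np.count_nonzero(z_max - pts[:, 2] < 0.5)


class TestKnnMeanDistances:
    def test_three_collinear_hand_computed(self):
        """Points at 0, 1, 2 with k = 2: ends average (1+2)/2, middle 1."""
        pts = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        state = ss.extract_top(pts, window=10.0)
        state = ss.knn_mean_distances(state, k_neighbors=2)
        order = np.argsort(pts[:, 0])
        np.testing.assert_allclose(state.mean_dists[order], [1.5, 1.0, 1.5])
        assert state.grand_mean == pytest.approx(4.0 / 3.0)

    def test_coincident_points(self):
        pts = np.zeros((5, 3))
        state = ss.knn_mean_distances(ss.extract_top(pts), k_neighbors=10)
        np.testing.assert_array_equal(state.mean_dists, np.zeros(5))
        assert state.grand_mean == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        pts = rng.normal(0, 1, size=(50, 3))
        pts[:, 2] *= 0.1  # keep all inside the top window
        state = ss.knn_mean_distances(ss.extract_top(pts, window=10.0))
        np.testing.assert_allclose(state.mean_dists, brute_knn_means(pts, 10))
        assert state.grand_mean == pytest.approx(state.mean_dists.mean())


class TestFilterTop:
    def test_isolated_spur_is_outlier(self, rng):
        crown = rng.normal(0, 0.05, size=(11, 3)) + [0, 0, 7.8]
        spur = np.array([[0.0, 0.0, 8.2]])
        pts = np.vstack([crown, spur])
        state = ss.knn_mean_distances(ss.extract_top(pts))
        tree, outliers, p_top = ss.filter_top(state)
        assert len(outliers) >= 1
        assert any(np.allclose(o, spur[0]) for o in outliers)
        assert p_top[2] < 8.2  # the spur never defines the top

    def test_uniform_grid_all_tree_points(self):
        g = np.linspace(0, 0.3, 4)
        pts = np.array([[x, y, 5.0] for x in g for y in g])
        state = ss.knn_mean_distances(ss.extract_top(pts), k_neighbors=3)
        # symmetric lattice rows: nobody is an outlier under <= comparison?
        tree, outliers, p_top = ss.filter_top(state)
        assert len(tree) >= 1
        # equality branch: perfectly coincident points are all kept
        state2 = ss.knn_mean_distances(ss.extract_top(np.zeros((6, 3))))
        tree2, out2, _ = ss.filter_top(state2)
        assert len(tree2) == 6 and len(out2) == 0

    def test_single_point_is_its_own_top(self):
        state = ss.knn_mean_distances(ss.extract_top(np.array([[1.0, 2.0, 3.0]])))
        tree, outliers, p_top = ss.filter_top(state)
        np.testing.assert_allclose(p_top, [1, 2, 3])

    def test_partition_never_empty(self, rng):
        """min(md_i) <= mean(md_i): the tree-point set cannot be empty."""
        for _ in range(20):
            pts = rng.normal(0, rng.uniform(0.01, 1.0), size=(int(rng.integers(2, 60)), 3))
            pts[:, 2] *= 0.05
            state = ss.knn_mean_distances(ss.extract_top(pts, window=10.0))
            tree, outliers, _ = ss.filter_top(state)
            assert len(tree) >= 1
            assert len(tree) + len(outliers) == state.m


class TestEstimateHeight:
    def test_examples(self):
        h, flags = ss.estimate_height([0, 0, 8.43], [0, 0, 0.0])
        assert h == pytest.approx(8.43) and flags == []
        h, _ = ss.estimate_height([5, 1, 8.0], [4, 2, 0.2])
        assert h == pytest.approx(7.8)

    def test_negative_clamped_and_flagged(self):
        h, flags = ss.estimate_height([0, 0, 1.0], [0, 0, 2.0])
        assert h == 0.0 and "negative_height_clamped" in flags

    def test_translation_invariance(self, rng):
        """Rigid horizontal translation of the tree leaves height unchanged."""
        pts = rng.normal(0, 0.1, size=(40, 3)) + [0, 0, 7.9]
        for offset in ([3.0, -2.0, 0.0], [100.0, 50.0, 0.0]):
            a = ss.knn_mean_distances(ss.extract_top(pts))
            b = ss.knn_mean_distances(ss.extract_top(pts + offset))
            _, _, top_a = ss.filter_top(a)
            _, _, top_b = ss.filter_top(b)
            ha, _ = ss.estimate_height(top_a, [0, 0, 0.1])
            hb, _ = ss.estimate_height(top_b, np.add([0, 0, 0.1], offset))
            assert ha == pytest.approx(hb, abs=1e-12)


class TestEstimateDbh:
    def test_noiseless_stem_recovers_diameter(self, coarse_config, single_stem_scene):
        plot, records, _ = single_stem_scene
        cloud = ss.build_cloud(records, coarse_config)
        dbh_cm, circle = ss.estimate_dbh(cloud, p_zero=[5.0, 0.0, -1.5])
        assert dbh_cm == pytest.approx(12.00, abs=0.01)
        assert (circle.xc, circle.yc) == pytest.approx((5.0, 0.0), abs=1e-3)

    def test_offset_ground_shifts_slice(self, coarse_config):
        """A stem on ground at z = 0.5 m is sliced at 1.8 m absolute."""
        ground = ss.GroundModel(z0=0.5)
        stem = ss.StemModel(x=4.0, y=0.0, dbh=0.12, height=8.0, taper=0.0)
        plot = ss.SyntheticPlot(extent=12.0, stems=[stem], ground=ground)
        records, _ = ss.simulate_scan(
            plot, scanner_pos=(0, 0, 2.0), config=coarse_config, seed=0
        )
        cloud = ss.build_cloud(records, coarse_config)
        # scanner frame: ground at -1.5, breast height at -0.2
        dbh_cm, circle = ss.estimate_dbh(cloud, p_zero=[4.0, 0.0, -1.5])
        assert dbh_cm == pytest.approx(12.0, abs=0.05)

    def test_too_few_points_raises(self):
        cloud = ss.PointCloud(xyz=np.zeros((5, 3)))
        with pytest.raises(DegenerateFitError):
            ss.estimate_dbh(cloud, p_zero=[0, 0, 0])


class TestProcessPlot:
    def test_empty_scene_empty_list(self, coarse_config):
        plot = ss.SyntheticPlot(extent=10.0, stems=[], ground=ss.GroundModel())
        records, _ = ss.simulate_scan(plot, config=coarse_config, seed=0)
        trees = ss.process_plot(records, scanner_config=coarse_config)
        assert trees == []

    def test_single_stem_closed_loop(self, coarse_config):
        """Noiseless single-stem scene: DBH to 0.1 cm, position to 1 cm,
        height to the top-of-tree discretization limit."""
        stem = ss.StemModel(x=4.0, y=1.0, dbh=0.14, height=7.5, taper=0.5)
        plot = ss.SyntheticPlot(
            extent=12.0, stems=[stem], ground=ss.GroundModel(),
            crown_spheres=np.zeros((0, 4)),
        )
        records, truth = ss.simulate_scan(
            plot, scanner_pos=(0, 0, 1.5), config=coarse_config, seed=0
        )
        trees = ss.process_plot(records, scanner_config=coarse_config, seed=0)
        assert len(trees) == 1
        t = trees[0]
        assert t.dbh_cm == pytest.approx(14.0, abs=0.1)
        assert np.hypot(t.x - 4.0, t.y - 1.0) < 0.01
        slant = np.hypot(np.hypot(4, 1), 7.5 - 1.5)
        spacing = 3 * slant * np.tan(np.deg2rad(coarse_config.delta_theta))
        assert t.height_m == pytest.approx(7.5, abs=max(spacing, 0.1))
        assert t.height_m <= 7.5 + 1e-6  # tops are never overshot

    def test_plantation_plot_counts(self, coarse_config):
        """All visible stems of a small simulated plot come back as records."""
        plot = ss.generate_plot(extent=8.0, vacancy_prob=0.0, seed=12)
        records, truth = ss.simulate_scan(
            plot, scanner_pos=(0.0, 0.0, 1.5), config=coarse_config, seed=3
        )
        trees = ss.process_plot(records, scanner_config=coarse_config, seed=0)
        est = np.array([[t.x, t.y] for t in trees])
        m = ss.match_trees(est, truth[["x_m", "y_m"]].to_numpy(), 0.5)
        assert m.correct >= len(truth) - 1  # at most one occlusion casualty
        assert m.false == 0

    def test_report_dataframe_schema(self, coarse_config, single_stem_scene):
        _, records, _ = single_stem_scene
        trees = ss.process_plot(records, scanner_config=coarse_config, seed=0)
        df = tree_records_to_dataframe(trees)
        assert list(df.columns) == [
            "id", "x_m", "y_m", "dbh_cm", "height_m", "ground_inclination_deg", "flags",
        ]
        assert len(df) == len(trees)
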