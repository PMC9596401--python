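"""Voronoi adjacency, window aggregation, weighted degree and transitivity."""

import itertools

import networkx as nx
import numpy as np
import pytest

from shoal import (
    aggregate_network,
    build_aggregated_networks,
    categorize_window,
    network_metrics_table,
    sensitivity_analysis,
    voronoi_adjacency,
    weighted_degree_metrics,
    weighted_transitivity,
)
from shoal.networks import AggregatedNetwork, to_networkx
from shoal.preprocess import FrameSet


def brute_force_delaunay(points: np.ndarray) -> set:
    """Empty-circumcircle test over all point triples (O(N^4) oracle)."""
    n = len(points)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = points[i], points[j], points[k]
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue  # degenerate triple
        ux = (
            np.dot(a, a) * (b[1] - c[1])
            + np.dot(b, b) * (c[1] - a[1])
            + np.dot(c, c) * (a[1] - b[1])
        ) / d
        uy = (
            np.dot(a, a) * (c[0] - b[0])
            + np.dot(b, b) * (a[0] - c[0])
            + np.dot(c, c) * (b[0] - a[0])
        ) / d
        center = np.array([ux, uy])
        r2 = np.sum((a - center) ** 2)
        others = [m for m in range(n) if m not in (i, j, k)]
        if all(np.sum((points[m] - center) ** 2) > r2 * (1 + 1e-10) for m in others):
            edges.update({(i, j), (i, k), (j, k)})
    return {tuple(sorted(e)) for e in edges}


def _star_network(n_fish=10):
    weights = {(0, j): 1.0 / (n_fish - 1) for j in range(1, n_fish)}
    return AggregatedNetwork(0.0, 600.0, n_fish, 150, 150, weights)


def _triangle(w01, w02, w12, n_fish=3):
    return AggregatedNetwork(
        0.0, 600.0, n_fish, 1, 1, {(0, 1): w01, (0, 2): w02, (1, 2): w12}
    )


class TestVoronoiAdjacency:
    def test_square_plus_center(self):
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [1.0, 1.01]])
        edges = voronoi_adjacency(pts)
        for corner in range(4):
            assert (corner, 4) in edges or (4, corner) in edges

    def test_triangle_with_relaxed_minimum(self):
        pts = np.array([[0, 0], [1, 0], [0.3, 1.2]])
        assert voronoi_adjacency(pts, min_fish=3) == [(0, 1), (0, 2), (1, 2)]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(5, 13))
            pts = rng.uniform(0, 30, (n, 2))
            edges = set(voronoi_adjacency(pts))
            assert edges == brute_force_delaunay(pts)
            assert len(edges) <= 3 * n - 6
            assert len(edges) >= n - 1

    def test_collinear_and_duplicate_points_resolved(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        edges = voronoi_adjacency(pts)
        assert len(edges) >= 5  # jitter makes the chain triangulable
        dup = np.array([[0, 0], [1, 1], [1, 1], [2, 0], [0, 2]], float)
        assert len(voronoi_adjacency(dup)) >= 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            voronoi_adjacency(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            voronoi_adjacency(np.zeros((4, 2)), min_fish=5)


class TestAggregation:
    def test_always_adjacent_pair_weight(self):
        edge_lists = [[(0, 1)]] * 150
        net = aggregate_network(edge_lists, n_fish=10)
        assert net.weights[(0, 1)] == pytest.approx(1.0 / 9.0)

    def test_partial_adjacency_weight(self):
        edge_lists = [[(0, 1)]] * 75 + [[]] * 75
        net = aggregate_network(edge_lists, n_fish=10)
        assert net.weights[(0, 1)] == pytest.approx(0.5 / 9.0)
        assert (2, 3) not in net.weights

    def test_skipped_frames_count_in_denominator(self):
        edge_lists = [[(0, 1)]] * 75 + [None] * 75
        net = aggregate_network(edge_lists, n_fish=10)
        assert net.weights[(0, 1)] == pytest.approx(0.5 / 9.0)
        assert net.n_graph_frames == 75

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            aggregate_network([], n_fish=10)


class TestWindowCategory:
    def test_threshold_strictly_greater(self):
        day = np.ones(100, bool)
        shade = np.zeros(100, bool)
        shade[:15] = True
        assert categorize_window(shade, day) == "shade_day"
        shade[:] = False
        shade[:10] = True
        assert categorize_window(shade, day) == "open_day"

    def test_night_window_ignores_position(self):
        shade = np.ones(50, bool)
        assert categorize_window(shade, np.zeros(50, bool)) == "night"

    def test_straddling_window_majority_rule(self):
        day = np.concatenate([np.ones(60, bool), np.zeros(40, bool)])
        shade = np.zeros(100, bool)
        assert categorize_window(shade, day) == "open_day"
        assert categorize_window(shade, ~day) == "night"


class TestMetrics:
    def test_star_degrees_match_worked_example(self):
        kappa, k = weighted_degree_metrics(_star_network())
        assert kappa[0] == pytest.approx(1.0)
        np.testing.assert_allclose(kappa[1:], 1.0 / 9.0)
        assert k == pytest.approx((1.0 + 9 * (1.0 / 9.0)) / 10.0)

    def test_complete_graph_saturates_degrees(self):
        n = 6
        weights = {(i, j): 1.0 / (n - 1) for i in range(n) for j in range(i + 1, n)}
        net = AggregatedNetwork(0.0, 600.0, n, 10, 10, weights)
        kappa, k = weighted_degree_metrics(net)
        np.testing.assert_allclose(kappa, 1.0)
        assert k == pytest.approx(1.0)

    def test_handshake_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 10))
            weights = {
                (i, j): rng.uniform(0, 1.0 / (n - 1))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.6
            }
            net = AggregatedNetwork(0.0, 600.0, n, 1, 1, weights)
            kappa, _ = weighted_degree_metrics(net)
            assert kappa.sum() == pytest.approx(2 * sum(weights.values()))

    def test_transitivity_equal_triangle_is_one(self):
        assert weighted_transitivity(_triangle(0.2, 0.2, 0.2)) == pytest.approx(1.0)

    def test_transitivity_path_is_zero(self):
        net = AggregatedNetwork(0.0, 600.0, 3, 1, 1, {(0, 1): 0.3, (1, 2): 0.3})
        assert weighted_transitivity(net) == 0.0

    def test_transitivity_uneven_triangle_is_half(self):
        w = 0.4
        assert weighted_transitivity(_triangle(w, w, w / 8)) == pytest.approx(0.5)

    def test_no_edges_gives_zero(self):
        assert weighted_transitivity(AggregatedNetwork(0, 600, 5, 1, 1, {})) == 0.0

    def test_matches_networkx_onnela_clustering(self, rng):
        """Cross-check against the independent NetworkX implementation."""
        for _ in range(20):
            n = int(rng.integers(5, 11))
            weights = {
                (i, j): rng.uniform(0.01, 1.0 / (n - 1))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.5
            }
            net = AggregatedNetwork(0.0, 600.0, n, 1, 1, weights)
            ours = weighted_transitivity(net)
            reference = np.mean(
                list(nx.clustering(to_networkx(net), weight="weight").values())
            )
            assert ours == pytest.approx(float(reference), abs=1e-12)


class TestWindowedPipeline:
    def test_windows_and_sensitivity_on_simulated_frames(self, mixed_run):
        from shoal import synchronize_tracks

        det = mixed_run["classified"]
        fs = synchronize_tracks(det[det.t < 7200.0], dt=4.0)
        nets = build_aggregated_networks(
            fs, mixed_run["geometry"], mixed_run["schedule"], window=600.0
        )
        assert 10 <= len(nets) <= 12
        table = network_metrics_table(nets)
        assert table.k.between(0, 1).all() and table.C.between(0, 1).all()
        sens = sensitivity_analysis(
            fs,
            mixed_run["geometry"],
            mixed_run["schedule"],
            windows=(300.0, 600.0),
            thresholds=(0.10, 0.20),
        )
        assert set(sens.window.unique()) == {300.0, 600.0}
        # medians vary smoothly with the window length choice
        for (_, th), sub in sens.groupby(["category", "threshold"]):
            if len(sub) == 2:
                assert abs(sub.median_k.diff().iloc[-1]) < 0.1
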