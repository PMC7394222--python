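"""Cost thresholding and weighted graph measures, including brute-force
and networkx oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dfcomplexity import (
    DynamicConnectivityTensor,
    clustering,
    cost_threshold,
    efficiency,
    n_edges_kept,
    nmts_from_tensor,
    strength,
)
from dfcomplexity.graphs import CostGrid

from conftest import random_symmetric


def brute_clustering(w):
    """Triple-enumeration Onnela clustering (independent oracle)."""
    n = w.shape[0]
    wmax = w.max()
    if wmax <= 0:
        return 0.0
    total = 0.0
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                acc += (w[i, j] * w[i, h] * w[j, h] / wmax**3) ** (1.0 / 3.0)
        total += acc / (k * (k - 1))
    return total / n


def nx_efficiency(w):
    """Weighted global efficiency via networkx shortest paths (oracle)."""
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    acc = 0.0
    d = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i in range(n):
        for j in range(n):
            if i != j and j in d.get(i, {}):
                acc += 1.0 / d[i][j]
    return acc / (n * (n - 1))


class TestCostThreshold:
    def test_paper_network_keeps_sixty_edges(self, rng):
        w = random_symmetric(rng, 19)
        out = cost_threshold(w, 0.35)
        assert n_edges_kept(19, 0.35) == 60  # round(0.35 * 171) = round(59.85)
        assert (np.triu(out, 1) > 0).sum() == 60

    def test_full_cost_is_identity(self, rng):
        w = random_symmetric(rng, 8)
        np.testing.assert_array_equal(cost_threshold(w, 1.0), w)

    def test_tie_break_deterministic(self):
        w = np.ones((5, 5)) - np.eye(5)
        out1 = cost_threshold(w, 0.5)
        out2 = cost_threshold(w, 0.5)
        assert (np.triu(out1, 1) > 0).sum() == 5
        np.testing.assert_array_equal(out1, out2)

    def test_kept_edges_are_strongest(self, rng):
        w = random_symmetric(rng, 10)
        out = cost_threshold(w, 0.2)
        kept = np.triu(out, 1)[np.triu(out, 1) > 0]
        dropped = np.triu(w - out, 1)[np.triu(w - out, 1) > 0]
        assert kept.min() >= dropped.max()


class TestStrength:
    def test_uniform_graph(self):
        w = 0.4 * (np.ones((19, 19)) - np.eye(19))
        assert strength(w) == pytest.approx(0.4)

    def test_empty_graph(self):
        assert strength(np.zeros((5, 5))) == 0.0

    def test_three_node_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.6
        w[1, 2] = w[2, 1] = 0.4
        assert strength(w) == pytest.approx(1.0 / 3.0)

    def test_nondecreasing_in_cost(self, rng):
        w = random_symmetric(rng, 12)
        vals = [strength(cost_threshold(w, k)) for k in CostGrid()]
        assert np.all(np.diff(vals) >= -1e-15)


class TestClustering:
    def test_binary_triangle(self):
        w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert clustering(w) == pytest.approx(1.0)

    def test_star_graph(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert clustering(w) == pytest.approx(0.0)

    def test_weighted_triangle_matches_brute_force(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[0, 2] = w[2, 0] = 0.6
        w[1, 2] = w[2, 1] = 0.4
        assert clustering(w) == pytest.approx(brute_clustering(w), abs=1e-12)

    def test_random_graphs_match_brute_force_and_networkx(self, rng):
        for n in (4, 5, 6):
            w = cost_threshold(random_symmetric(rng, n), 0.6)
            ours = clustering(w)
            assert ours == pytest.approx(brute_clustering(w), abs=1e-12)
            g = nx.from_numpy_array(w)
            assert ours == pytest.approx(
                np.mean(list(nx.clustering(g, weight="weight").values())), abs=1e-9
            )


class TestEfficiency:
    def test_two_nodes(self):
        w = np.array([[0.0, 0.7], [0.7, 0.0]])
        assert efficiency(w) == pytest.approx(0.7)

    def test_binary_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert efficiency(w) == pytest.approx(5.0 / 6.0)

    def test_complete_binary_graph(self):
        w = np.ones((6, 6)) - np.eye(6)
        assert efficiency(w) == pytest.approx(1.0)

    def test_disconnected_pairs_contribute_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0  # two isolated nodes remain
        assert efficiency(w) == pytest.approx(2.0 / 12.0)

    def test_random_graphs_match_networkx(self, rng):
        for n in (4, 5, 6):
            w = cost_threshold(random_symmetric(rng, n), 0.5)
            assert efficiency(w) == pytest.approx(nx_efficiency(w), abs=1e-12)


class TestMeasureInvariances:
    def test_node_relabeling_invariance(self, rng):
        w = cost_threshold(random_symmetric(rng, 7), 0.4)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        for fn in (strength, clustering, efficiency):
            assert fn(w) == pytest.approx(fn(wp), abs=1e-12)


class TestNMTS:
    def test_constant_tensor_gives_constant_series(self):
        w = np.tile(0.5 * (np.ones((4, 4)) - np.eye(4)), (10, 1, 1))
        t = DynamicConnectivityTensor(w, np.arange(10))
        for m in ("D", "C", "E"):
            vals = nmts_from_tensor(t, 0.5, m).values
            assert np.ptp(vals) < 1e-12

    def test_fast_paths_agree_with_per_slice_reference(self, rng):
        w = np.stack([random_symmetric(rng, 8) for _ in range(25)])
        t = DynamicConnectivityTensor(w, np.arange(25))
        for k in (0.2, 0.35, 0.5):
            d_fast = nmts_from_tensor(t, k, "D").values
            c_fast = nmts_from_tensor(t, k, "C").values
            d_ref = [strength(cost_threshold(sl, k)) for sl in w]
            c_ref = [clustering(cost_threshold(sl, k)) for sl in w]
            np.testing.assert_allclose(d_fast, d_ref, atol=1e-12)
            np.testing.assert_allclose(c_fast, c_ref, atol=1e-12)

    def test_series_length_matches_tensor(self, rng):
        w = np.stack([random_symmetric(rng, 5) for _ in range(7)])
        t = DynamicConnectivityTensor(w, np.arange(7))
        assert len(nmts_from_tensor(t, 0.3, "E")) == 7
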