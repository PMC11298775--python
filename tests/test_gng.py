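"""Growing-neural-gas graph: winner search, adaptation arithmetic,
component structure, streaming classification and drift tracking."""
import numpy as np
import pytest

from gemsort import FeatureVector, GngParams, Graph, adapt, cluster_components, nearest_two, sort_stream
from gemsort.core import SpikeEvent


def _graph(positions, params=None):
    g = Graph(params or GngParams())
    for p in positions:
        g.add_node(np.atleast_1d(np.asarray(p, dtype=float)))
    return g


def _fv(x, t=0, channel=0):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    spike = SpikeEvent(channel, t, np.zeros(4), 0.0)
    return FeatureVector(channel_feature=x[0], coeffs=x[1:], spike=spike)


class TestNearestTwo:
    def test_direct_distances(self):
        g = _graph([0.0, 10.0])
        w1, w2, d1, d2 = nearest_two(g, np.array([1.0]))
        assert (w1, w2) == (0, 1)
        assert d1 == pytest.approx(1.0) and d2 == pytest.approx(9.0)

    def test_query_on_node(self):
        g = _graph([0.0, 10.0])
        _, _, d1, _ = nearest_two(g, np.array([10.0]))
        assert d1 == 0.0

    def test_tie_breaks_to_lower_id(self):
        g = _graph([0.0, 2.0])
        w1, _, _, _ = nearest_two(g, np.array([1.0]))
        assert w1 == 0

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(50, 3))
        g = _graph(pts)
        for _ in range(200):
            x = rng.normal(size=3)
            w1, w2, d1, d2 = nearest_two(g, x)
            d = np.linalg.norm(pts - x, axis=1)
            order = np.argsort(d, kind="stable")
            assert (w1, w2) == (order[0], order[1])
            assert d1 == pytest.approx(d[order[0]])

    def test_requires_two_nodes(self):
        with pytest.raises(ValueError):
            nearest_two(_graph([0.0]), np.array([1.0]))


class TestAdaptArithmetic:
    def test_winner_moves_by_e_s1(self):
        g = _graph([0.0, 10.0])
        adapt(g, np.array([1.0]))
        assert g.positions[0][0] == pytest.approx(0.8)  # 0 + 0.8*(1-0)

    def test_winner_update_is_exact_contraction(self, rng):
        g = _graph(rng.normal(size=(5, 2)))
        for _ in range(20):
            x = rng.normal(size=2)
            w1, _, d1, _ = nearest_two(g, x)
            before = np.linalg.norm(g.positions[w1] - x)
            adapt(g, x)
            if w1 in g.positions:
                after = np.linalg.norm(g.positions[w1] - x)
                assert after == pytest.approx((1 - 0.8) * before, abs=1e-12)

    def test_neighbour_moves_by_e_nbr(self):
        g = _graph([0.0, 10.0])
        g._set_edge(0, 1, 0)
        adapt(g, np.array([1.0]))  # W1 = node 0, neighbour = node 1
        assert g.positions[1][0] == pytest.approx(10.0 + 0.001 * (1.0 - 10.0))

    def test_winner_error_accumulates_squared_distance(self):
        g = _graph([0.0, 10.0])
        adapt(g, np.array([3.0]))
        assert g.errors[0] == pytest.approx(9.0)

    def test_two_blob_stream_classified_purely(self, rng):
        params = GngParams(max_nodes=30)
        g = Graph(params)
        centres = np.array([[0.0, 0.0], [10.0, 10.0]])
        labels_true, labels_out = [], []
        for i in range(600):
            which = int(rng.integers(2))
            x = centres[which] + rng.normal(0, 0.4, size=2)
            if g.n_nodes < 2:
                g.add_node(x)
                continue
            labels_true.append(which)
            labels_out.append(adapt(g, x))
        true = np.asarray(labels_true[300:])
        out = np.asarray(labels_out[300:])
        purity = 0
        for lab in np.unique(out):
            vals, counts = np.unique(true[out == lab], return_counts=True)
            purity += counts.max()
        assert purity / out.size > 0.95

    def test_node_budget_respected(self, rng):
        params = GngParams(max_nodes=12)
        g = Graph(params)
        for _ in range(500):
            x = rng.normal(size=2) * 5
            if g.n_nodes < 2:
                g.add_node(x)
            else:
                adapt(g, x)
            assert 1 <= g.n_nodes <= 12


class TestClusterComponents:
    def test_single_edge_single_cluster(self):
        g = _graph([0.0, 1.0])
        g._set_edge(0, 1, 0)
        assert len(set(cluster_components(g).values())) == 1

    def test_two_disjoint_edges_two_clusters(self):
        g = _graph([0.0, 1.0, 5.0, 6.0])
        g._set_edge(0, 1, 0)
        g._set_edge(2, 3, 0)
        assert len(set(cluster_components(g).values())) == 2

    def test_matches_networkx_reachability(self, rng):
        import networkx as nx

        for _ in range(100):
            n = int(rng.integers(2, 30))
            g = _graph(rng.normal(size=(n, 2)), GngParams(max_nodes=64))
            nxg = nx.Graph()
            nxg.add_nodes_from(range(n))
            for _ in range(int(rng.integers(0, 2 * n))):
                a, b = rng.integers(0, n, size=2)
                if a != b:
                    g._set_edge(int(a), int(b), 0)
                    nxg.add_edge(int(a), int(b))
            mine = cluster_components(g)
            for comp in nx.connected_components(nxg):
                assert len({mine[v] for v in comp}) == 1
            assert len(set(mine.values())) == nx.number_connected_components(nxg)


class TestSortStream:
    def test_empty_stream(self):
        result = sort_stream([], GngParams())
        assert result.n_spikes == 0

    def test_deterministic(self, rng):
        xs = rng.normal(size=(300, 3))
        feats = [_fv(x, t=i) for i, x in enumerate(xs)]
        a = sort_stream(feats, GngParams(max_nodes=24))
        b = sort_stream(feats, GngParams(max_nodes=24))
        assert np.array_equal(a.cluster_ids, b.cluster_ids)

    def test_eight_blob_stream_recovers_blobs(self, rng):
        centres = np.array([[c, 0.0, 0.0] for c in (0, 3, 5, 7, 9, 11, 13, 15)], dtype=float)
        which = rng.integers(0, 8, size=2400)
        xs = centres[which] + np.concatenate(
            [np.zeros((2400, 1)), rng.normal(0, 0.1, size=(2400, 2))], axis=1
        )
        feats = [_fv(x, t=i) for i, x in enumerate(xs)]
        result = sort_stream(feats, GngParams(max_nodes=192))
        out = result.cluster_ids[1200:]
        true = which[1200:]
        purity = sum(
            np.bincount(true[out == lab]).max() for lab in np.unique(out)
        )
        assert len(np.unique(out)) >= 8
        assert purity / out.size > 0.9

    def test_memory_bounded_by_node_budget(self, rng):
        params = GngParams(max_nodes=16)
        g = Graph(params)
        feats = [_fv(rng.normal(size=2) * 3, t=i) for i in range(1000)]
        sort_stream(feats, params, g)
        assert g.n_nodes <= 16


def test_drift_adaptation_recovers_purity(rng):
    """Translate all blob centres mid-stream: after a recovery period the
    per-spike purity returns to within 5% of its pre-shift level."""
    centres = np.array([[0.0, 0.0], [8.0, 0.0], [4.0, 7.0]])
    shift = np.array([20.0, 5.0])
    params = GngParams(max_nodes=30)
    g = Graph(params)
    pre_true, pre_out, post_true, post_out = [], [], [], []
    n_pre, n_post = 900, 1200
    warmup = 300
    for i in range(n_pre + n_post):
        which = int(rng.integers(3))
        x = centres[which] + rng.normal(0, 0.4, size=2)
        if i >= n_pre:
            x = x + shift
        if g.n_nodes < 2:
            g.add_node(x)
            continue
        lab = adapt(g, x)
        if warmup <= i < n_pre:
            pre_true.append(which)
            pre_out.append(lab)
        elif i >= n_pre + 5 * warmup // 3:  # after ~5x the warm-up budget
            post_true.append(which)
            post_out.append(lab)

    def purity(true, out):
        true, out = np.asarray(true), np.asarray(out)
        return sum(
            np.bincount(true[out == lab]).max() for lab in np.unique(out)
        ) / out.size

    assert purity(post_true, post_out) >= purity(pre_true, pre_out) - 0.05
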