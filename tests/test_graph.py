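"""Tile-graph construction and hyperedge attention aggregation."""

import numpy as np
import pytest

from glstm.dataio import CaseProfile, TileID
from glstm.graph import (
    AttentionParams,
    CaseEdge,
    TileGraph,
    aggregate_case_edges,
    aggregate_features,
    build_tile_graph,
    edge_attention,
    edge_representation,
)

from conftest import make_feature


def _case(case_id, tile, counts_by_cat, n_weeks=3):
    weekly = {}
    for cat, week_counts in counts_by_cat.items():
        weekly[cat] = np.asarray(week_counts, dtype=int)
    return CaseProfile(case_id=case_id, tile=tile, weekly_counts=weekly)


TILE = TileID(10, 300, 380)


class TestBuildTileGraph:
    def test_two_pois_one_case_single_clique(self):
        feats = [make_feature("p1", ("A1",), [0, 0, 0]), make_feature("p2", ("A1",), [0, 0, 0])]
        g = build_tile_graph(feats, [_case("c1", TILE, {"A1": [1, 0, 0]})], week=1, tile=TILE)
        assert np.array_equal(g.A, np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert len(g.edges) == 1
        assert g.edges[0].member_pois == (0, 1)

    def test_no_cases_gives_empty_graph(self):
        feats = [make_feature(f"p{i}", ("A2",), [0, 0]) for i in range(3)]
        g = build_tile_graph(feats, [], week=1, tile=TILE)
        assert not g.A.any()
        assert g.edges == []

    def test_disjoint_categories_give_two_components(self):
        # two venue groups under categories A1 and A2 stay disconnected
        feats = [
            make_feature("a1", ("A1",), [0]), make_feature("a2", ("A1",), [0]),
            make_feature("b1", ("A2",), [0]), make_feature("b2", ("A2",), [0]),
        ]
        cases = [
            _case("c1", TILE, {"A1": [2]}, n_weeks=1),
            _case("c2", TILE, {"A2": [1]}, n_weeks=1),
        ]
        g = build_tile_graph(feats, cases, week=1, tile=TILE)
        assert g.A[0, 1] == 1 and g.A[2, 3] == 1
        assert g.A[0, 2] == g.A[0, 3] == g.A[1, 2] == g.A[1, 3] == 0

    def test_zero_weekly_count_contributes_no_edge(self):
        feats = [make_feature("p1", ("A1",), [0, 0]), make_feature("p2", ("A1",), [0, 0])]
        g = build_tile_graph(feats, [_case("c1", TILE, {"A1": [0, 3]})], week=1, tile=TILE)
        assert g.edges == []
        g2 = build_tile_graph(feats, [_case("c1", TILE, {"A1": [0, 3]})], week=2, tile=TILE)
        assert len(g2.edges) == 1

    def test_empty_tile_rejected(self):
        with pytest.raises(ValueError):
            build_tile_graph([], [], week=1, tile=TILE)

    def test_unknown_category_rejected(self):
        feats = [make_feature("p1", ("A1",), [0])]
        bad = CaseProfile("cx", TILE, {"A99": np.array([1])})
        with pytest.raises(ValueError):
            build_tile_graph(feats, [bad], week=1, tile=TILE)

    def test_adjacency_is_deterministic(self):
        feats = [make_feature(f"p{i}", ("A1" if i % 2 else "A3",), [1, 2]) for i in range(6)]
        cases = [_case("c1", TILE, {"A1": [1, 1], "A3": [2, 0]})]
        g1 = build_tile_graph(feats, cases, week=1, tile=TILE)
        g2 = build_tile_graph(feats, cases, week=1, tile=TILE)
        assert np.array_equal(g1.A, g2.A)
        assert g1.node_ids == g2.node_ids


class TestEdgeAttention:
    def test_singleton_edge_gets_unit_weight(self):
        feats = [make_feature("p1", ("A1",), [2])]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        params = AttentionParams.init(g.X.shape[1], K=1, rng=np.random.default_rng(0))
        alpha = edge_attention(g.edges[0], g, params)
        assert alpha.shape == (1, 1)
        assert alpha[0, 0] == pytest.approx(1.0)

    def test_identical_features_get_uniform_weights(self):
        feats = [make_feature(f"p{i}", ("A1",), [3], lat=1.0, lng=1.0) for i in range(4)]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        params = AttentionParams.init(g.X.shape[1], K=2, rng=np.random.default_rng(1))
        alpha = edge_attention(g.edges[0], g, params)
        assert np.allclose(alpha, 0.25)

    def test_matches_termwise_softmax_oracle(self):
        rng = np.random.default_rng(5)
        feats = [
            make_feature(f"p{i}", ("A1",), [int(rng.integers(5))],
                         lat=float(rng.uniform(0, 10)), lng=float(rng.uniform(0, 10)))
            for i in range(4)
        ]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        d = g.X.shape[1]
        params = AttentionParams.init(d, K=1, rng=rng)
        alpha = edge_attention(g.edges[0], g, params)[0]
        # independent term-by-term oracle
        P = g.X
        c0 = P.mean(axis=0)
        scores = []
        for j in range(4):
            z = np.concatenate([params.W_c @ c0, params.W[0] @ P[j]])
            s = float(params.b[0] @ z)
            scores.append(s if s > 0 else params.leaky_slope * s)
        e = np.exp(np.array(scores) - max(scores))
        assert np.allclose(alpha, e / e.sum(), atol=1e-12)

    def test_coefficients_sum_to_one(self):
        rng = np.random.default_rng(6)
        feats = [make_feature(f"p{i}", ("A1",), [int(rng.integers(9))]) for i in range(7)]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        params = AttentionParams.init(g.X.shape[1], K=3, rng=rng)
        alpha = edge_attention(g.edges[0], g, params)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
        assert (alpha > 0).all()


class TestAggregation:
    def test_single_member_identity_projection(self):
        feats = [make_feature("p1", ("A1",), [2])]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        d = g.X.shape[1]
        params = AttentionParams(
            K=1, W_c=np.eye(d), W=[np.eye(d)], b=[np.zeros(2 * d)]
        )
        rep = edge_representation(g.X[[0]], params)
        assert np.allclose(rep, g.X[0])

    def test_two_identical_heads_equal_one_head(self):
        rng = np.random.default_rng(8)
        feats = [make_feature(f"p{i}", ("A1",), [int(rng.integers(5))]) for i in range(3)]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        d = g.X.shape[1]
        W = rng.uniform(-0.5, 0.5, (d, d))
        Wc = rng.uniform(-0.5, 0.5, (d, d))
        b = rng.uniform(-0.5, 0.5, 2 * d)
        one = AttentionParams(K=1, W_c=Wc, W=[W], b=[b])
        two = AttentionParams(K=2, W_c=Wc, W=[W, W.copy()], b=[b, b.copy()])
        assert np.allclose(
            aggregate_case_edges(g, one), aggregate_case_edges(g, two), atol=1e-12
        )

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        feats = [
            make_feature(f"p{i}", ("A1",), [int(rng.integers(5))],
                         lat=float(rng.uniform(0, 10)), lng=float(rng.uniform(0, 10)))
            for i in range(3)
        ]
        g = build_tile_graph(feats, [_case("c", TILE, {"A1": [1]}, 1)], week=1, tile=TILE)
        d = g.X.shape[1]
        params = AttentionParams.init(d, K=2, rng=rng)
        # hand-rolled double loop over heads and members (attention seeded
        # with the member mean, before aggregation caches representations)
        P = g.X
        alpha = edge_attention(g.edges[0], g, params)
        out = aggregate_case_edges(g, params)
        c_n = np.zeros(d)
        for k in range(2):
            for j in range(3):
                c_n += alpha[k, j] * (params.W_c @ P[j])
        c_n /= 2.0
        expected = P + c_n[None, :]  # one incident edge per node
        assert np.allclose(out, expected, atol=1e-10)

    def test_duplicate_case_edges_weight_the_writeback(self):
        # node in two A1 edges and one A3 edge: mean weights A1's vector 2/3
        feats = [make_feature("p1", ("A1", "A3"), [1]), make_feature("p2", ("A1",), [2])]
        cases = [
            _case("c1", TILE, {"A1": [1]}, 1),
            _case("c2", TILE, {"A1": [1]}, 1),
            _case("c3", TILE, {"A3": [1]}, 1),
        ]
        g = build_tile_graph(feats, cases, week=1, tile=TILE)
        d = g.X.shape[1]
        params = AttentionParams.init(d, K=1, rng=np.random.default_rng(2))
        out = aggregate_case_edges(g, params)
        rep_a1 = edge_representation(g.X[[0, 1]], params)
        rep_a3 = edge_representation(g.X[[0]], params)
        assert np.allclose(out[0], g.X[0] + (2 * rep_a1 + rep_a3) / 3.0, atol=1e-12)
        assert np.allclose(out[1], g.X[1] + rep_a1, atol=1e-12)

    def test_no_edges_rejected(self):
        feats = [make_feature("p1", ("A1",), [1])]
        g = build_tile_graph(feats, [], week=1, tile=TILE)
        params = AttentionParams.init(g.X.shape[1], K=1)
        with pytest.raises(ValueError):
            aggregate_case_edges(g, params)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        n, d = 5, 13
        X = rng.normal(size=(n, d))
        members = np.array([0, 2, 3])
        params = AttentionParams.init(d, K=1, rng=rng)
        out = aggregate_features(X, [(members, 1)], params)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        out_p = aggregate_features(X[perm], [(inv[members], 1)], params)
        assert np.allclose(out_p[inv], out, atol=1e-10)
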