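"""Construct graph typologies, degree and Presence-Balance centrality, layouts."""

import numpy as np
import pandas as pd
import pytest

from wimpgrid import (
    CONGRUENT,
    DILEMMATIC,
    DISCREPANT,
    UNDEFINED_SELF,
    build_digraph,
    classify_edge,
    classify_node,
    compute_weights,
    layout,
    pb_index,
    weighted_degrees,
)


def degrees_oracle(W, mode):
    n = W.shape[0]
    f = abs if mode == "absolute" else (lambda v: v)
    k_out = [sum(f(W[i, j]) for j in range(n)) for i in range(n)]
    k_in = [sum(f(W[j, i]) for j in range(n)) for i in range(n)]
    return np.array(k_in), np.array(k_out)


class TestClassifyNode:
    @pytest.mark.parametrize(
        "s,d,expected",
        [
            (2 / 3, 1.0, CONGRUENT),
            (-2 / 3, 1.0, DISCREPANT),
            (0.0, 1.0, UNDEFINED_SELF),
            (0.5, 0.0, DILEMMATIC),
            (0.0, 0.0, UNDEFINED_SELF),  # undefined self takes precedence
            (-0.5, -0.5, CONGRUENT),
        ],
    )
    def test_categories(self, s, d, expected):
        assert classify_node(s, d) == expected


class TestClassifyEdge:
    @pytest.mark.parametrize(
        "w,s_i,s_j,expected",
        [
            (0.4, 0.5, 0.5, "direct"),
            (0.4, -0.5, 0.5, "inverse"),
            (-0.4, -0.5, -0.5, "inverse"),
            (-0.4, 0.5, -0.5, "direct"),
            (0.4, 0.0, 0.5, "direct"),  # undefined self displays the right pole
        ],
    )
    def test_sign_conjugation(self, w, s_i, s_j, expected):
        assert classify_edge(w, s_i, s_j) == expected

    def test_zero_weight_is_not_an_edge(self):
        with pytest.raises(ValueError):
            classify_edge(0.0, 0.5, 0.5)


class TestBuildDigraph:
    def test_zero_matrix_yields_no_edges(self, demo):
        G = build_digraph(demo, np.zeros((5, 5)))
        assert G.number_of_nodes() == 5 and G.number_of_edges() == 0

    def test_demo_grid_node_categories(self, demo):
        G = build_digraph(demo, compute_weights(demo))
        cats = {G.nodes[i]["label"]: G.nodes[i]["category"] for i in G.nodes}
        assert cats["Sick-Healthy"] == CONGRUENT
        assert cats["No sporty-Sporty"] == UNDEFINED_SELF
        assert cats["Lazy-Hardworker"] == DISCREPANT
        assert cats["Calm-Anxious"] == DISCREPANT
        assert cats["Free-Busy"] == DILEMMATIC

    def test_node_size_is_self_definition(self, demo):
        G = build_digraph(demo, compute_weights(demo))
        for i in G.nodes:
            assert G.nodes[i]["size"] == abs(demo.s[i])
            assert 0.0 <= G.nodes[i]["size"] <= 1.0

    def test_threshold_drops_small_edges(self, demo):
        W = np.zeros((5, 5))
        W[0, 1] = 0.25
        W[1, 2] = 0.5
        G = build_digraph(demo, W, epsilon=0.3)
        assert list(G.edges) == [(1, 2)]

    def test_edge_count_monotone_in_threshold(self, demo, grid_factory):
        g = grid_factory(seed=7, n=8)
        W = compute_weights(g)
        counts = [build_digraph(g, W, eps).number_of_edges() for eps in (0.0, 0.1, 0.3, 0.6, 2.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0


class TestWeightedDegrees:
    def test_hand_sums_absolute(self):
        W = np.array([[0.0, -0.5], [0.25, 0.0]])
        deg = weighted_degrees(W)
        np.testing.assert_allclose(deg["k_out"], [0.5, 0.25])
        np.testing.assert_allclose(deg["k_in"], [0.25, 0.5])
        np.testing.assert_allclose(deg["k"], [0.75, 0.75])

    def test_hand_sums_signed(self):
        W = np.array([[0.0, -0.5], [0.25, 0.0]])
        deg = weighted_degrees(W, mode="signed")
        np.testing.assert_allclose(deg["k_out"], [-0.5, 0.25])

    def test_zero_matrix(self):
        deg = weighted_degrees(np.zeros((4, 4)))
        assert (deg.values == 0).all()

    @pytest.mark.parametrize("mode", ["absolute", "signed"])
    def test_matches_loop_oracle(self, rng, mode):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            # dyadic-lattice weights: sums are exact in any accumulation order
            W = rng.integers(-128, 129, (n, n)) / 64.0
            np.fill_diagonal(W, 0.0)
            deg = weighted_degrees(W, mode=mode)
            k_in, k_out = degrees_oracle(W, mode)
            np.testing.assert_array_equal(deg["k_in"].values, k_in)
            np.testing.assert_array_equal(deg["k_out"].values, k_out)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            weighted_degrees(np.zeros((2, 2)), mode="other")


class TestPBIndex:
    def test_hand_rotation(self):
        deg = pd.DataFrame({"k_in": [0.3], "k_out": [0.5], "k": [0.8]})
        pb = pb_index(deg)
        assert pb["presence"].iloc[0] == pytest.approx(0.56569, abs=1e-5)
        assert pb["balance"].iloc[0] == pytest.approx(0.14142, abs=1e-5)

    def test_balanced_construct_has_zero_balance(self):
        deg = pd.DataFrame({"k_in": [1.0, 0.0], "k_out": [1.0, 0.0], "k": [2.0, 0.0]})
        pb = pb_index(deg)
        np.testing.assert_array_equal(pb["balance"], [0.0, 0.0])
        assert pb["presence"].iloc[1] == 0.0

    def test_orthonormal_rotation_preserves_norm(self, rng):
        for _ in range(500):
            deg = pd.DataFrame({"k_in": rng.uniform(0, 5, 6), "k_out": rng.uniform(0, 5, 6)})
            pb = pb_index(deg)
            np.testing.assert_allclose(
                pb["presence"] ** 2 + pb["balance"] ** 2,
                deg["k_in"] ** 2 + deg["k_out"] ** 2,
                atol=1e-12,
            )

    def test_feasible_region_under_absolute_degrees(self, grid_factory):
        for seed in range(100):
            W = compute_weights(grid_factory(seed, n=6))
            pb = pb_index(weighted_degrees(W))
            assert np.all(pb["presence"] >= np.abs(pb["balance"]) - 1e-12)

    def test_literal_factor_breaks_orthonormality(self):
        deg = pd.DataFrame({"k_in": [1.0], "k_out": [0.0]})
        pb = pb_index(deg, factor=0.52)
        assert pb["presence"].iloc[0] == pytest.approx(0.52)


class TestLayout:
    @pytest.mark.parametrize("method", ["reingold_tilford", "graphopt", "mds"])
    def test_finite_coordinates(self, demo, method):
        G = build_digraph(demo, compute_weights(demo))
        xy = layout(G, method, seed=1)
        assert xy.shape == (5, 2)
        assert np.isfinite(xy.values).all()

    @pytest.mark.parametrize("method", ["graphopt", "mds"])
    def test_seeded_determinism(self, demo, method):
        G = build_digraph(demo, compute_weights(demo))
        a = layout(G, method, seed=9)
        b = layout(G, method, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_node_graph(self, demo):
        import networkx as nx

        G = nx.DiGraph()
        G.add_node(0)
        for method in ("reingold_tilford", "graphopt", "mds"):
            assert layout(G, method).shape == (1, 2)

    def test_mds_collapses_identical_profiles(self, demo):
        # constructs 0 and 1 get identical implication profiles
        W = np.zeros((5, 5))
        W[0, 2] = W[1, 2] = 0.5
        W[3, 0] = W[3, 1] = -0.4
        G = build_digraph(demo, W)
        xy = layout(G, "mds").values
        assert np.linalg.norm(xy[0] - xy[1]) < 1e-9

    def test_unknown_method(self, demo):
        G = build_digraph(demo, np.zeros((5, 5)))
        with pytest.raises(ValueError):
            layout(G, "spring")
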