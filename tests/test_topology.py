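"""Thresholding, density grids, and graph metrics against independent oracles."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from scovnet import (
    DensityGrid,
    binarize_at_density,
    characteristic_path_length,
    clustering_coefficient,
    find_dmin,
    global_efficiency,
    identify_hubs,
    metric_curves,
    nodal_betweenness,
    nodal_degree,
    small_worldness,
)
from scovnet.topology import adjacency_stack, edge_count_at_density, rank_edges


def graph_to_adj(g: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(g, dtype=np.int8)


# ---------------------------------------------------------------------------
# brute-force oracles (pure-python enumeration, independent of the fast paths)


def brute_distances(A):
    n = len(A)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0)
    for length in range(1, n):
        P = np.linalg.matrix_power(np.asarray(A, dtype=np.int64), length)
        for i in range(n):
            for j in range(n):
                if P[i, j] > 0 and D[i, j] == np.inf:
                    D[i, j] = length
    return D


def brute_betweenness(A):
    """Enumerate every simple path per pair; count fractions of shortest ones."""
    n = len(A)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = []

        def extend(path):
            last = path[-1]
            if last == t:
                paths.append(tuple(path))
                return
            for nxt in range(n):
                if A[last][nxt] and nxt not in path:
                    extend(path + [nxt])

        extend([s])
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            bc[v] += through / len(sp)
    return bc


def brute_clustering(A):
    n = len(A)
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if A[v][u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if A[a][b])
        out[v] = 2 * links / (k * (k - 1))
    return out


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_edge_count_formula(self):
        assert edge_count_at_density(4, 0.5) == 3
        assert edge_count_at_density(105, 0.1) == round(0.1 * 105 * 104 / 2)

    def test_keeps_largest_weights(self):
        W = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        W[iu] = [0.9, 0.1, 0.8, 0.2, 0.7, 0.3]
        W = W + W.T
        A = binarize_at_density(W, 0.5)
        assert A.sum() // 2 == 3
        kept = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if A[i, j]}
        assert kept == {(0, 1), (0, 3), (1, 3)}  # the 0.9, 0.8, 0.7 edges

    def test_full_density_complete_graph(self):
        W = np.random.default_rng(0).normal(size=(6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        A = binarize_at_density(W, 1.0)
        assert (nodal_degree(A) == 5).all()

    def test_tie_break_deterministic_by_index(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        W[0, 2] = W[2, 0] = 0.9
        A1 = binarize_at_density(W, 2 / 6)
        A2 = binarize_at_density(W.copy(), 2 / 6)
        assert (A1 == A2).all()
        assert A1[0, 1] == 1 and A1[2, 3] == 0  # (0,1) precedes (2,3) lexicographically

    def test_negative_edges_warn(self):
        W = -np.ones((4, 4)) * 0.5
        np.fill_diagonal(W, 0)
        with pytest.warns(UserWarning, match="negative"):
            binarize_at_density(W, 0.5)

    def test_invalid_density(self):
        W = np.eye(3)
        with pytest.raises(ValueError):
            binarize_at_density(W, 0.0)
        with pytest.raises(ValueError):
            binarize_at_density(W, 1.5)

    def test_nested_edge_sets_along_grid(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(12, 12))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        stack = adjacency_stack(W, DensityGrid(0.1, 0.9, 0.1))
        for lo, hi in zip(stack.adjacency, stack.adjacency[1:]):
            assert ((lo == 1) <= (hi == 1)).all()
        n = 12
        for d, k in zip(stack.grid.densities, stack.edge_counts):
            assert k == int(np.floor(d * n * (n - 1) / 2 + 0.5))


class TestDmin:
    def test_spanning_tree_toy(self):
        W = np.zeros((4, 4))
        for (i, j), w in zip([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
                             [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]):
            W[i, j] = W[j, i] = w
        assert find_dmin([W], step=0.5) == 0.5
        # brute-force oracle over a fine grid
        fine = find_dmin([W], step=0.01)
        for d in np.arange(0.01, 1.001, 0.01):
            from scipy.sparse.csgraph import connected_components

            A = binarize_at_density(W, min(d, 1.0))
            if connected_components(A, directed=False)[0] == 1:
                assert fine == pytest.approx(round(d, 10))
                break

    def test_complete_weights_connect_at_first_step(self):
        n = 6
        W = np.ones((n, n)) - np.eye(n)
        # a clique's top-k edges may still isolate nodes at tiny k: find the
        # smallest grid density and verify by construction
        d = find_dmin([W], step=0.1)
        A = binarize_at_density(W, d)
        from scipy.sparse.csgraph import connected_components

        assert connected_components(A, directed=False)[0] == 1

    def test_isolated_low_weight_node_raises_dmin(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0.5, 1.0, (6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        W2 = np.zeros((7, 7))
        W2[:6, :6] = W
        W2[6, :6] = W2[:6, 6] = 1e-6
        assert find_dmin([W2], step=0.02) >= find_dmin([W], step=0.02)

    def test_multiple_groups_use_worst_case(self):
        W_easy = np.ones((4, 4)) - np.eye(4)
        W_hard = np.zeros((4, 4))
        for (i, j), w in zip([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
                             [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]):
            W_hard[i, j] = W_hard[j, i] = w
        assert find_dmin([W_easy, W_hard], 0.25) == find_dmin([W_hard], 0.25)


class TestMetricExamples:
    def test_path_graph_degrees(self):
        A = graph_to_adj(nx.path_graph(3))
        assert list(nodal_degree(A)) == [1, 2, 1]

    def test_star_degrees_and_handshake(self):
        A = graph_to_adj(nx.star_graph(4))
        deg = nodal_degree(A)
        assert deg[0] == 4 and (deg[1:] == 1).all()
        assert deg.sum() == 2 * (A.sum() // 2)

    def test_star_betweenness_center(self):
        A = graph_to_adj(nx.star_graph(3))  # 4-node star
        bc = nodal_betweenness(A)
        assert bc[0] == pytest.approx(3.0)  # C(3,2) leaf pairs
        assert np.allclose(bc[1:], 0.0)

    def test_path_length_examples(self):
        complete = graph_to_adj(nx.complete_graph(5))
        assert characteristic_path_length(complete) == (pytest.approx(1.0), True)
        path3 = graph_to_adj(nx.path_graph(3))
        L, connected = characteristic_path_length(path3)
        assert L == pytest.approx(4 / 3)
        assert connected

    def test_disconnected_path_length_restricted_and_flagged(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1  # one edge, two isolated nodes
        L, connected = characteristic_path_length(A)
        assert L == pytest.approx(1.0)
        assert not connected

    def test_efficiency_examples(self):
        assert global_efficiency(graph_to_adj(nx.complete_graph(4))) == pytest.approx(1.0)
        assert global_efficiency(graph_to_adj(nx.path_graph(3))) == pytest.approx(
            (1 + 1 + 0.5) / 3
        )
        assert global_efficiency(np.zeros((5, 5), dtype=int)) == 0.0

    def test_clustering_examples(self):
        tri_local, tri_global = clustering_coefficient(graph_to_adj(nx.complete_graph(3)))
        assert np.allclose(tri_local, 1.0) and tri_global == pytest.approx(1.0)
        path_local, path_global = clustering_coefficient(graph_to_adj(nx.path_graph(4)))
        assert np.allclose(path_local, 0.0) and path_global == 0.0

    def test_small_worldness(self):
        tri = graph_to_adj(nx.complete_graph(3))
        assert small_worldness(tri, c_rand=1.0, l_rand=1.0) == pytest.approx(1.0)
        # halving the null clustering doubles sigma (linearity in C/C_rand)
        assert small_worldness(tri, 0.5, 1.0) == pytest.approx(
            2 * small_worldness(tri, 1.0, 1.0)
        )
        with pytest.raises(ValueError):
            small_worldness(tri, 0.0, 1.0)

    def test_lattice_is_small_world_against_random_nulls(self):
        ring = graph_to_adj(nx.watts_strogatz_graph(20, 6, 0.0, seed=1))
        rng = np.random.default_rng(4)
        cs, ls = [], []
        n_edges = int(ring.sum() // 2)
        for _ in range(20):
            g = nx.gnm_random_graph(20, n_edges, seed=int(rng.integers(2**31)))
            A = graph_to_adj(g)
            cs.append(clustering_coefficient(A)[1])
            ls.append(characteristic_path_length(A)[0])
        assert small_worldness(ring, float(np.mean(cs)), float(np.mean(ls))) > 1.0


class TestHubs:
    def test_regular_graph_has_no_hubs(self):
        deg = {f"n{i}": 4 for i in range(10)}
        assert identify_hubs(deg).hubs == []

    def test_star_center_is_only_hub(self):
        A = graph_to_adj(nx.star_graph(5))
        deg = dict(zip([f"n{i}" for i in range(6)], nodal_degree(A).tolist()))
        assert identify_hubs(deg, k_sd=2.0).hubs == ["n0"]

    def test_k_zero_selects_above_mean(self):
        deg = {"a": 1, "b": 2, "c": 3}
        assert set(identify_hubs(deg, k_sd=0.0).hubs) == {"c"}


class TestCurves:
    def test_degree_and_efficiency_monotone_in_density(self):
        rng = np.random.default_rng(8)
        W = rng.normal(size=(15, 15))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        curves = metric_curves(W, DensityGrid(0.2, 0.6), ("degree", "global_efficiency"))
        for c in curves:
            assert (np.diff(c.values) >= -1e-12).all()

    def test_singleton_grid_single_value(self):
        W = np.ones((5, 5)) - np.eye(5)
        curves = metric_curves(W, DensityGrid(0.4, 0.4), ("degree",))
        assert all(len(c.values) == 1 for c in curves)


class TestOracleEquivalence:
    """Metrics agree with exhaustive enumeration on every graph of <= 6 nodes.

    The networkx atlas lists all non-isomorphic graphs up to 7 nodes; every
    metric is invariant under node relabeling, so covering the atlas covers
    all graphs of <= 6 nodes.
    """

    @pytest.fixture(scope="class")
    def small_graphs(self):
        from networkx.generators.atlas import graph_atlas_g

        return [g for g in graph_atlas_g() if 1 <= g.number_of_nodes() <= 6]

    def test_all_metrics_match_brute_force(self, small_graphs):
        assert len(small_graphs) == 208
        for g in small_graphs:
            A = graph_to_adj(g)
            n = len(A)
            D = brute_distances(A)
            # degree
            assert (nodal_degree(A) == A.sum(axis=1)).all()
            # betweenness
            np.testing.assert_allclose(
                nodal_betweenness(A), brute_betweenness(A.tolist()), atol=1e-9
            )
            # path length over connected pairs
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(D) & off
            L, _ = characteristic_path_length(A)
            if finite.sum():
                assert L == pytest.approx(D[finite].mean())
            else:
                assert np.isnan(L)
            # efficiency
            inv = np.where(finite, 1.0 / np.where(D == 0, np.inf, D), 0.0)
            assert global_efficiency(A) == pytest.approx(
                inv[off].mean() if n > 1 else 0.0
            )
            # clustering
            np.testing.assert_allclose(
                clustering_coefficient(A)[0], brute_clustering(A.tolist()), atol=1e-9
            )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        W = rng.normal(size=(7, 7))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        A = binarize_at_density(W, 0.4)
        for perm in list(permutations(range(7)))[:20]:
            P = np.eye(7)[list(perm)]
            Ap = (P @ A @ P.T).astype(np.int8)
            assert sorted(nodal_degree(A)) == sorted(nodal_degree(Ap))
            assert characteristic_path_length(A)[0] == pytest.approx(
                characteristic_path_length(Ap)[0]
            )
            assert global_efficiency(A) == pytest.approx(global_efficiency(Ap))
            assert clustering_coefficient(A)[1] == pytest.approx(
                clustering_coefficient(Ap)[1]
            )
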