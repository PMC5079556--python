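import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from firebreaks import (
    CAParams,
    CentralityError,
    FireSpreadNetwork,
    betweenness,
    bonacich,
    build_network,
    closeness,
    edge_distance,
    eigencentrality,
    generate_artificial_forest,
    rank_nodes,
)

from conftest import make_full_grid, make_simple_grid


# ---------------------------------------------------------------------------
# Fixtures and oracles
# ---------------------------------------------------------------------------


def random_network(n: int, seed: int, density: float = 0.15) -> FireSpreadNetwork:
    """Random weighted digraph wrapped as a fire-spread network."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    weights = rng.uniform(0.1, 1.0, (n, n)) * mask
    return FireSpreadNetwork(adjacency=sp.csr_matrix(weights), n_rows=1, n_cols=n)


def strongly_connected_network(n: int, seed: int) -> FireSpreadNetwork:
    """Directed cycle plus random chords: strongly connected by construction."""
    rng = np.random.default_rng(seed)
    weights = np.zeros((n, n))
    for i in range(n):
        weights[i, (i + 1) % n] = rng.uniform(0.2, 1.0)
    extra = rng.random((n, n)) < 0.2
    np.fill_diagonal(extra, False)
    weights = np.where(extra & (weights == 0), rng.uniform(0.1, 1.0, (n, n)), weights)
    return FireSpreadNetwork(adjacency=sp.csr_matrix(weights), n_rows=1, n_cols=n)


def to_networkx(net: FireSpreadNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_nodes))
    coo = net.adjacency.tocoo()
    for u, v, w in zip(coo.row, coo.col, coo.data):
        g.add_edge(int(u), int(v), dist=1.0 / w)
    return g


def closeness_oracle(net: FireSpreadNetwork) -> np.ndarray:
    """Formula assembled from networkx single-source Dijkstra lengths."""
    g = to_networkx(net)
    n = net.n_nodes
    out = np.zeros(n)
    for k in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, k, weight="dist")
        lengths.pop(k, None)
        if lengths:
            out[k] = 1.0 / (sum(lengths.values()) * (len(lengths) / (n - 1)))
    return out


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


class TestBuildNetwork:
    def test_uniform_torus_edge_count_and_weights(self, torus3_half):
        net = build_network(torus3_half)
        assert net.n_nodes == 9
        assert net.adjacency.nnz == 72
        assert np.allclose(net.adjacency.data, 0.5)

    def test_out_degree_bounded_and_zero_diagonal(self, forest50):
        net = build_network(forest50)
        out_deg = np.diff(net.adjacency.indptr)
        assert (out_deg <= 8).all()
        assert net.adjacency.diagonal().sum() == 0

    def test_simple_model_in_edges_share_target_weight(self, forest50):
        net = build_network(forest50)
        csc = net.adjacency.tocsc()
        k = forest50.node_index(7, 9)
        in_weights = csc.data[csc.indptr[k] : csc.indptr[k + 1]]
        assert np.allclose(in_weights, 1.0 - forest50.emptiness[7, 9])

    def test_flat_homogeneous_full_model_weights_are_nominal(self):
        grid = make_full_grid(
            np.full((4, 4), "other"), np.full((4, 4), "moderate")
        )
        net = build_network(grid, CAParams())
        assert np.allclose(net.adjacency.data, 0.58)

    def test_empty_cell_is_isolated(self):
        emptiness = np.full((4, 4), 0.4)
        emptiness[1, 2] = 1.0
        net = build_network(make_simple_grid(emptiness))
        k = 1 * 4 + 2
        assert net.adjacency[:, k].nnz == 0
        assert net.adjacency[k, :].nnz == 0


class TestEdgeDistance:
    def test_reciprocal_values(self):
        assert edge_distance(1.0) == 1.0
        assert edge_distance(0.5) == 2.0

    def test_distance_reverses_weight_order(self):
        w = np.array([0.2, 0.9, 0.5, 0.31])
        d = edge_distance(w)
        assert (np.argsort(d) == np.argsort(-w)).all()

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(CentralityError):
            edge_distance(0.0)

    def test_neglog_variant(self):
        assert edge_distance(np.exp(-2.0), "neglog") == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# Centrality measures vs oracles
# ---------------------------------------------------------------------------


class TestBetweenness:
    def test_directed_path_center_scores_one(self):
        adj = sp.csr_matrix(np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=float))
        net = FireSpreadNetwork(adjacency=adj, n_rows=1, n_cols=3)
        scores = betweenness(net).scores
        assert scores[1] == pytest.approx(1.0)
        assert scores[0] == scores[2] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_path_counting(self, seed):
        net = random_network(25, seed)
        ours = betweenness(net).scores
        oracle = nx.betweenness_centrality(
            to_networkx(net), normalized=False, weight="dist"
        )
        assert np.allclose(ours, [oracle[k] for k in range(25)], rtol=1e-8, atol=1e-10)

    def test_needs_three_nodes(self):
        net = FireSpreadNetwork(sp.csr_matrix(np.array([[0.0, 1], [1, 0]])), 1, 2)
        with pytest.raises(CentralityError):
            betweenness(net)


class TestCloseness:
    def test_two_node_chain(self):
        adj = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        net = FireSpreadNetwork(adjacency=adj, n_rows=1, n_cols=2)
        scores = closeness(net).scores
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == 0.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_dijkstra_sums(self, seed):
        net = random_network(22, seed)
        assert np.allclose(
            closeness(net).scores, closeness_oracle(net), rtol=1e-8, atol=1e-12
        )


class TestEigencentrality:
    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_dense_eigendecomposition(self, seed):
        net = strongly_connected_network(20, seed)
        ours = eigencentrality(net).scores
        at = net.adjacency.toarray().T
        vals, vecs = np.linalg.eig(at)
        i = np.argmax(np.abs(vals))
        vec = np.abs(np.real(vecs[:, i]))
        assert np.allclose(ours, vec / vec.sum(), rtol=1e-7, atol=1e-9)
        assert net.lambda_max == pytest.approx(np.real(vals[i]), rel=1e-8)

    def test_scale_invariance(self):
        net = strongly_connected_network(18, 7)
        scaled = FireSpreadNetwork(net.adjacency * 0.37, 1, 18)
        assert np.allclose(
            eigencentrality(net).scores, eigencentrality(scaled).scores, atol=1e-8
        )

    def test_scores_nonnegative_unit_sum(self, forest50):
        scores = eigencentrality(build_network(forest50)).scores
        assert (scores >= 0).all()
        assert scores.sum() == pytest.approx(1.0)


class TestBonacich:
    @pytest.mark.parametrize("beta", [0.2, 0.5, 0.8])
    def test_matches_dense_linear_solve(self, beta):
        net = strongly_connected_network(20, 8)
        ours = bonacich(net, beta).scores
        at = net.adjacency.toarray().T
        lam = np.max(np.real(np.linalg.eigvals(at)))
        expected = np.linalg.solve(np.eye(20) - (beta / lam) * at, np.ones(20))
        assert np.allclose(ours, expected, rtol=1e-8)

    def test_beta_zero_reduces_to_weighted_in_degree(self):
        net = random_network(15, 9)
        scores = bonacich(net, 0.0).scores
        in_degree = np.asarray(net.adjacency.sum(axis=0)).ravel()
        assert np.allclose(scores, in_degree)
        # the literal solve at beta=0 is the constant vector
        solved = np.linalg.solve(np.eye(15), np.ones(15))
        assert np.allclose(solved, 1.0)
        assert (rank_nodes(scores) == rank_nodes(in_degree)).all()

    def test_beta_near_one_approaches_eigencentrality_ranking(self):
        net = strongly_connected_network(12, 10)
        top_bona = rank_nodes(bonacich(net, 0.995).scores)[:4]
        top_eig = rank_nodes(eigencentrality(net).scores)[:4]
        assert list(top_bona) == list(top_eig)

    def test_beta_at_or_above_one_rejected(self):
        net = random_network(10, 11)
        with pytest.raises(CentralityError):
            bonacich(net, 1.0)


# ---------------------------------------------------------------------------
# Structural properties
# ---------------------------------------------------------------------------


MEASURES = {
    "betweenness": lambda net: betweenness(net).scores,
    "closeness": lambda net: closeness(net).scores,
    "eigen": lambda net: eigencentrality(net).scores,
    "bonacich": lambda net: bonacich(net, 0.5).scores,
}


class TestStructuralProperties:
    @pytest.mark.parametrize("name", MEASURES)
    def test_uniform_torus_scores_are_constant(self, name):
        grid = make_simple_grid(np.full((5, 5), 0.5))
        scores = MEASURES[name](build_network(grid))
        assert np.allclose(scores, scores[0], rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("name", MEASURES)
    def test_permutation_equivariance(self, name):
        net = strongly_connected_network(14, 12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(14)
        p_mat = sp.csr_matrix(
            (np.ones(14), (perm, np.arange(14))), shape=(14, 14)
        )
        # relabeling i -> perm[i]: A'[perm[i], perm[j]] = A[i, j]
        permuted = FireSpreadNetwork(p_mat @ net.adjacency @ p_mat.T, 1, 14)
        base = MEASURES[name](net)
        relabeled = MEASURES[name](permuted)
        assert np.allclose(relabeled[perm], base, rtol=1e-6, atol=1e-9)

    def test_adjacency_exports_to_matrix_market(self, tmp_path, torus3_half):
        from firebreaks import build_network, write_adjacency_mtx
        import scipy.io as sio

        net = build_network(torus3_half)
        path = tmp_path / "adj.mtx"
        write_adjacency_mtx(net, path)
        back = sio.mmread(path)
        assert np.allclose(back.toarray(), net.adjacency.toarray())

    def test_shortest_path_measures_ignore_weight_scaling(self):
        net = strongly_connected_network(15, 13)
        scaled = FireSpreadNetwork(net.adjacency * 0.25, 1, 15)
        assert np.allclose(
            betweenness(net).scores, betweenness(scaled).scores, atol=1e-9
        )
        assert (
            rank_nodes(closeness(net).scores)
            == rank_nodes(closeness(scaled).scores)
        ).all()
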